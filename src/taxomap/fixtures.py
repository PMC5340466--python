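"""Synthetic data generators: every capability is testable offline.

Random taxonomic forests with observations, random DNA with plantable primer
binding sites (and a truth table of where they were planted), and two-group
abundance matrices with plantable fold-change effects.  Each generator is
fully deterministic given its seed and returns both the data object and the
generating ground truth, so round-trip and recovery oracles can be exact.

The abundance baseline is long-tailed (log-normal taxon weights) to mimic
the rank-abundance shape of real microbiome profiles; what these fixtures do
not emulate (real database taxonomy shapes, sequencing error, compositional
artefacts) is spelled out in the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Taxmap, TaxmapError
from .pcr import IUPAC_SETS, PrimerPair, reverse_complement

DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the generators (defaults = the study conditions of the tests)."""

    n_taxa: int = 50
    n_roots: int = 1
    max_depth: int = 5
    branching: float = 2.5  # mean children per internal taxon
    n_obs: int = 100
    ranks: tuple = DEFAULT_RANKS
    seq_length: int = 150
    planted_primer_fraction: float = 1.0
    n_samples_per_group: int = 10
    library_size: int = 10000
    abundance_sigma: float = 1.5  # log-normal spread of baseline taxon weights
    effect_taxa: tuple = ()  # ((taxon_row_index, fold_change), ...) applied in group B
    seed: int = 0

    def __post_init__(self):
        if min(self.n_taxa, self.n_roots, self.max_depth, self.n_obs,
               self.n_samples_per_group, self.library_size, self.seq_length) <= 0:
            raise TaxmapError("all fixture counts must be positive")
        if not 0.0 <= self.planted_primer_fraction <= 1.0:
            raise TaxmapError("planted_primer_fraction must be in [0, 1]")
        if self.n_roots > self.n_taxa:
            raise TaxmapError("n_roots cannot exceed n_taxa")


@dataclass
class GeneratedTaxmap:
    """A random Taxmap plus its generating structure (the round-trip oracle)."""

    taxmap: Taxmap
    parent: dict[str, str | None]
    depth: dict[str, int]
    lineages: dict[str, tuple[str, ...]]  # taxon -> root-path of names


def random_taxmap(cfg: FixtureConfig, seed: int | None = None) -> GeneratedTaxmap:
    """Draw a random forest by sequential parent attachment.

    Each new taxon attaches uniformly to an existing taxon that is above
    ``max_depth`` and still has spare child capacity (capacity drawn around
    ``branching``); the first ``n_roots`` taxa are roots.  Ranks follow
    depth; observations land on uniformly chosen taxa.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = [f"t_{k + 1}" for k in range(cfg.n_taxa)]
    names = [f"Tax{k + 1}" for k in range(cfg.n_taxa)]
    capacity = 1 + rng.poisson(max(cfg.branching - 1.0, 0.0), size=cfg.n_taxa)
    parent: dict[str, str | None] = {}
    depth: dict[str, int] = {}
    n_children = np.zeros(cfg.n_taxa, dtype=int)
    for k in range(cfg.n_taxa):
        if k < cfg.n_roots:
            parent[ids[k]] = None
            depth[ids[k]] = 0
            continue
        eligible = [j for j in range(k)
                    if depth[ids[j]] < cfg.max_depth - 1 and n_children[j] < capacity[j]]
        if not eligible:
            eligible = [j for j in range(k) if depth[ids[j]] < cfg.max_depth - 1]
        if not eligible:
            raise TaxmapError(
                f"cannot place taxon {k + 1}: max_depth={cfg.max_depth} with "
                f"branching={cfg.branching} leaves no eligible parent")
        j = int(eligible[rng.integers(len(eligible))])
        parent[ids[k]] = ids[j]
        depth[ids[k]] = depth[ids[j]] + 1
        n_children[j] += 1

    taxa = pd.DataFrame({
        "taxon_id": ids,
        "supertaxon_id": [parent[t] for t in ids],
        "name": names,
        "rank": [cfg.ranks[min(depth[t], len(cfg.ranks) - 1)] for t in ids],
    })
    obs_taxa = rng.integers(cfg.n_taxa, size=cfg.n_obs)
    obs = pd.DataFrame({
        "obs_id": [f"o_{k + 1}" for k in range(cfg.n_obs)],
        "taxon_id": [ids[j] for j in obs_taxa],
    })
    tm = Taxmap(taxa, obs)
    name_of = dict(zip(ids, names))
    lineages = {}
    for t in ids:
        path = [t]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        lineages[t] = tuple(name_of[x] for x in reversed(path))
    return GeneratedTaxmap(taxmap=tm, parent=parent, depth=depth, lineages=lineages)


def _realize(primer: str, rng: np.random.Generator) -> str:
    """One concrete ACGT realization of a degenerate primer."""
    return "".join(IUPAC_SETS[c][rng.integers(len(IUPAC_SETS[c]))] for c in primer.upper())


def _inject_mismatches(seq: list[str], start: int, probe: str, n_mm: int,
                       rng: np.random.Generator) -> int:
    """Corrupt ``n_mm`` positions of a planted site so they no longer match
    the (possibly degenerate) probe; returns the number actually injected."""
    candidates = [i for i, c in enumerate(probe.upper()) if c != "N"]
    rng.shuffle(candidates)
    injected = 0
    for i in candidates[:n_mm]:
        allowed = set(IUPAC_SETS[probe.upper()[i]])
        bad = [b for b in "ACGT" if b not in allowed]
        seq[start + i] = bad[rng.integers(len(bad))]
        injected += 1
    return injected


def random_sequences(cfg: FixtureConfig, n: int, primers: PrimerPair | None = None,
                     seed: int | None = None,
                     mismatch_choices=(0,)) -> tuple[list[str], pd.DataFrame]:
    """Random ACGT sequences, optionally with planted primer binding sites.

    For a fraction ``cfg.planted_primer_fraction`` of the sequences a
    realized forward primer and a downstream reverse-complemented reverse
    primer are inserted at recorded positions, each corrupted with a number
    of mismatches drawn from ``mismatch_choices``.  Returns the sequences
    and a truth table (planted, fwd_start, rev_start, fwd_mm, rev_mm).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = cfg.seq_length
    bases = np.array(list("ACGT"))
    rows = []
    seqs = []
    for _ in range(n):
        seq = list(bases[rng.integers(4, size=L)])
        row = {"planted": False, "fwd_start": -1, "rev_start": -1,
               "fwd_mm": 0, "rev_mm": 0}
        if primers is not None and rng.random() < cfg.planted_primer_fraction:
            lf, lr = len(primers.forward), len(primers.reverse)
            if L < lf + lr + 2:
                raise TaxmapError(
                    f"seq_length={L} too short to plant primers of length {lf}+{lr}")
            fwd_start = int(rng.integers(0, L - lf - lr - 1))
            rev_start = int(rng.integers(fwd_start + lf + 1, L - lr + 1))
            fwd_site = _realize(primers.forward, rng)
            rev_probe = reverse_complement(primers.reverse)
            rev_site = _realize(rev_probe, rng)
            seq[fwd_start:fwd_start + lf] = list(fwd_site)
            seq[rev_start:rev_start + lr] = list(rev_site)
            fwd_mm = int(np.asarray(mismatch_choices)[rng.integers(len(mismatch_choices))])
            rev_mm = int(np.asarray(mismatch_choices)[rng.integers(len(mismatch_choices))])
            row = {"planted": True, "fwd_start": fwd_start, "rev_start": rev_start,
                   "fwd_mm": _inject_mismatches(seq, fwd_start, primers.forward, fwd_mm, rng),
                   "rev_mm": _inject_mismatches(seq, rev_start, rev_probe, rev_mm, rng)}
        seqs.append("".join(seq))
        rows.append(row)
    return seqs, pd.DataFrame(rows)


def random_abundance(cfg: FixtureConfig, taxon_ids=None,
                     seed: int | None = None) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Two-group abundance matrix with optional planted fold changes.

    Baseline taxon weights are log-normal (long-tailed); per-sample counts
    are multinomial at ``library_size`` reads.  ``cfg.effect_taxa`` entries
    ``(row_index, fold)`` multiply a taxon's weight in group B only.
    Returns (counts, sample->group labels, truth).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ids = list(taxon_ids) if taxon_ids is not None else [f"t_{k + 1}" for k in range(cfg.n_taxa)]
    n = len(ids)
    w = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n)
    w_b = w.copy()
    for idx, fold in cfg.effect_taxa:
        if not 0 <= idx < n:
            raise TaxmapError(f"effect taxon index {idx} out of range")
        w_b[idx] *= fold
    cols = {}
    groups = {}
    for g, weights in (("A", w), ("B", w_b)):
        p = weights / weights.sum()
        for s in range(cfg.n_samples_per_group):
            name = f"{g}{s + 1}"
            cols[name] = rng.multinomial(cfg.library_size, p)
            groups[name] = g
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="taxon_id"))
    truth = {"baseline_weights": w, "effect_taxa": tuple(cfg.effect_taxa)}
    return counts, pd.Series(groups), truth
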