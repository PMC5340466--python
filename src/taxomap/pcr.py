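"""Native digital (in-silico) PCR.

Predicts amplification success of degenerate primer pairs against reference
sequences: ungapped binding-site search under a mismatch budget expressed as
a percentage of primer length, pairing of a forward site with a downstream
reverse-complemented reverse-primer site, and per-taxon summaries (proportion
of subtree sequences amplified) ready for heat-tree coloring.

IUPAC degenerate codes are matched by set intersection (``N`` matches
anything, ``R`` matches ``A``/``G``/``R``/... — any code sharing a base).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Taxmap, TaxmapError

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _m in _MASK.items():
    _MASK_TABLE[ord(_c)] = _m
    _MASK_TABLE[ord(_c.lower())] = _m

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_match(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect."""
    try:
        return bool(_MASK[a.upper()] & _MASK[b.upper()])
    except KeyError:
        bad = a if a.upper() not in _MASK else b
        raise TaxmapError(f"non-IUPAC character: {bad!r}") from None


def _encode(seq: str, what: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    masks = _MASK_TABLE[arr]
    if np.any(masks == 0):
        pos = int(np.argmax(masks == 0))
        raise TaxmapError(f"non-IUPAC character {seq[pos]!r} in {what} at position {pos}")
    return masks


def reverse_complement(s: str) -> str:
    """Reverse complement honouring degenerate codes (R<->Y, K<->M, B<->V, ...)."""
    _encode(s, "sequence")  # alphabet check
    return s.upper().translate(_COMPLEMENT)[::-1]


def mismatch_budget(primer: str, max_mismatch_percent: float) -> int:
    """floor(percent/100 x primer length) — percent-of-length semantics."""
    return math.floor(max_mismatch_percent / 100.0 * len(primer))


def find_sites(primer: str, template: str, max_mismatch_percent: float) -> list[dict]:
    """All ungapped primer placements within the mismatch budget.

    Returns ``[{"start": offset, "mismatches": count}, ...]`` ordered by
    offset (0-based).  A primer longer than the template yields no sites.
    """
    if not primer:
        raise TaxmapError("empty primer")
    p = _encode(primer, "primer")
    t = _encode(template, "template")
    L = len(p)
    if L > len(t):
        return []
    budget = mismatch_budget(primer, max_mismatch_percent)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    mismatches = np.count_nonzero((windows & p) == 0, axis=1)
    hits = np.nonzero(mismatches <= budget)[0]
    return [{"start": int(i), "mismatches": int(mismatches[i])} for i in hits]


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair, both written 5'->3' on their own strands."""

    forward: str
    reverse: str
    max_mismatch_percent: float = 0.0

    def __post_init__(self):
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise TaxmapError(f"{name} primer is empty")
            _encode(p, f"{name} primer")
        if not 0.0 <= self.max_mismatch_percent <= 100.0:
            raise TaxmapError("max_mismatch_percent must be in [0, 100]")


def _best_product(fwd_sites, rev_sites, fwd_len, rev_len,
                  min_len, max_len) -> dict | None:
    best = None
    for f in fwd_sites:
        for r in rev_sites:
            if r["start"] < f["start"] + fwd_len:
                continue  # reverse site must be strictly downstream of the forward site
            start, end = f["start"], r["start"] + rev_len
            length = end - start
            if (min_len is not None and length < min_len) or \
               (max_len is not None and length > max_len):
                continue
            key = (length, start)
            if best is None or key < best[0]:
                best = (key, {"product_start": start, "product_end": end,
                              "product_length": length,
                              "fwd_mismatches": f["mismatches"],
                              "rev_mismatches": r["mismatches"]})
    return None if best is None else best[1]


def amplify(sequence: str, primers: PrimerPair, *, both_strands: bool = False,
            min_product_length: int | None = None,
            max_product_length: int | None = None) -> dict:
    """Amplification outcome of one template.

    A template amplifies iff a forward-primer site exists and a
    reverse-complemented reverse-primer site lies strictly downstream of the
    forward site's end.  Among qualifying site pairs the shortest product
    wins (tie: leftmost forward site).  Coordinates are 0-based half-open on
    the scanned strand.
    """
    pct = primers.max_mismatch_percent
    rev_probe = reverse_complement(primers.reverse)

    def scan(seq):
        return _best_product(
            find_sites(primers.forward, seq, pct),
            find_sites(rev_probe, seq, pct),
            len(primers.forward), len(primers.reverse),
            min_product_length, max_product_length)

    hit = scan(sequence)
    strand = "+"
    if both_strands:
        hit_rc = scan(reverse_complement(sequence))
        if hit_rc is not None and (hit is None or
                                   hit_rc["product_length"] < hit["product_length"]):
            hit, strand = hit_rc, "-"
    out = {"amplified": hit is not None, "product_start": None, "product_end": None,
           "product_length": None, "fwd_mismatches": None, "rev_mismatches": None}
    if hit is not None:
        out.update(hit)
    if both_strands:
        out["strand"] = strand if hit is not None else None
    return out


def _subtree_sums(tm: Taxmap, per_obs: np.ndarray) -> np.ndarray:
    """Sum a per-observation quantity over each taxon's subtree."""
    idx = tm._index()
    totals = {t: 0.0 for t in tm.taxon_ids}
    for t, v in zip(tm.obs["taxon_id"], per_obs):
        totals[t] += v
    for t in reversed(tm._topo_order()):
        p = idx.parent[t]
        if p is not None:
            totals[p] += totals[t]
    return np.array([totals[t] for t in tm.taxon_ids], dtype=float)


def _n_amplified(tm: Taxmap) -> np.ndarray:
    return _subtree_sums(tm, tm.obs["amplified"].to_numpy(dtype=float)).astype(np.int64)


def _n_not_amplified(tm: Taxmap) -> np.ndarray:
    return tm._subtree_obs_counts() - _n_amplified(tm)


def _prop_amplified(tm: Taxmap) -> np.ndarray:
    n = tm._subtree_obs_counts()
    amp = _n_amplified(tm)
    with np.errstate(invalid="ignore"):
        prop = np.where(n > 0, amp / np.maximum(n, 1), 0.0)
    return prop


def digital_pcr(tm: Taxmap, primers: PrimerPair, sequence_column: str = "sequence",
                *, both_strands: bool = False, min_product_length: int | None = None,
                max_product_length: int | None = None) -> Taxmap:
    """Run digital PCR over every observation sequence.

    Returns a new Taxmap whose observation table gains ``amplified``,
    ``product_start/end/length`` and ``fwd/rev_mismatches`` columns, and
    whose taxon computed-column registry gains ``n_amplified``,
    ``n_not_amplified`` and ``prop_amplified`` (amplified fraction of each
    taxon's subtree observations; 0 for taxa with no observations).  The
    computed columns re-evaluate after any subsequent filtering.
    """
    if sequence_column not in tm.obs.columns:
        raise TaxmapError(f"observation table has no {sequence_column!r} column")
    results = [amplify(seq, primers, both_strands=both_strands,
                       min_product_length=min_product_length,
                       max_product_length=max_product_length)
               for seq in tm.obs[sequence_column]]
    obs = tm.obs.copy()
    res = pd.DataFrame(results, index=obs.index)
    obs["amplified"] = res["amplified"].astype(bool)
    for col in ("product_start", "product_end", "product_length",
                "fwd_mismatches", "rev_mismatches"):
        obs[col] = pd.array(res[col], dtype="Int64")
    if both_strands:
        obs["strand"] = res["strand"]
    out = tm._replace(obs=obs)
    out.register_taxon_func("n_amplified", _n_amplified)
    out.register_taxon_func("n_not_amplified", _n_not_amplified)
    out.register_taxon_func("prop_amplified", _prop_amplified)
    return out


def amplification_summary(tm: Taxmap) -> pd.DataFrame:
    """Per-taxon summary table (taxon_id, name, n_obs, n_amplified, prop_amplified)."""
    if "amplified" not in tm.obs.columns:
        raise TaxmapError("run digital_pcr first (no 'amplified' column)")
    return pd.DataFrame({
        "taxon_id": tm.taxon_ids,
        "name": tm.taxa.get("name", tm.taxa["taxon_id"]),
        "n_obs": tm._subtree_obs_counts(),
        "n_amplified": _n_amplified(tm),
        "prop_amplified": _prop_amplified(tm),
    })
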