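"""Universal parsing of taxonomic information from text.

Most reference databases embed classifications in free-text headers, each in
its own dialect (``Bacteria;Firmicutes;...``, ``k__Bacteria;p__Firmicutes``,
tab-separated lineage columns, ...).  Instead of one parser per dialect, a
single :func:`parse_records` is driven by a :class:`ParseSpec`: a regular
expression whose capture groups are named by a *key* that says which group
carries the classification and which carry per-observation metadata.

Shared lineage prefixes are merged, so the result is a deduplicated
:class:`~taxomap.core.Taxmap` edge list with one observation per input text.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .core import Taxmap, TaxmapError

logger = logging.getLogger("taxomap")

ROLES = ("class", "taxon_name", "taxon_id", "obs_info")


@dataclass(frozen=True)
class ParseSpec:
    """How to read classification out of one text record.

    ``key`` has one entry per capture group of ``regex``; each entry is a role
    tag, optionally suffixed ``:column_name`` for ``obs_info`` captures:

    - ``class`` — a full lineage string, split on ``class_separator`` into
      levels (root-most first unless ``reverse_levels``), each level
      optionally split on ``rank_separator`` into ``rank<sep>name``.
    - ``taxon_name`` — a single taxon name (one-level lineage).
    - ``taxon_id`` — a database taxon identifier, kept verbatim as a taxon
      column ``source_taxon_id`` (no online resolution is attempted).
    - ``obs_info`` — carried into the observation table as a column.
    """

    regex: str
    key: tuple[str, ...]
    class_separator: str = ";"
    rank_separator: str | None = None
    reverse_levels: bool = False

    def __post_init__(self):
        object.__setattr__(self, "key", tuple(self.key))
        pattern = re.compile(self.regex)
        if pattern.groups != len(self.key):
            raise ValueError(
                f"regex has {pattern.groups} capture groups but key has {len(self.key)} entries"
            )
        roles = [k.split(":", 1)[0] for k in self.key]
        for r in roles:
            if r not in ROLES:
                raise ValueError(f"unknown key role {r!r}; expected one of {ROLES}")
        for r in ("class", "taxon_name", "taxon_id"):
            if roles.count(r) > 1:
                raise ValueError(f"role {r!r} may appear at most once")
        if not any(r in roles for r in ("class", "taxon_name", "taxon_id")):
            raise ValueError("key must contain a classification-bearing role "
                             "(class, taxon_name or taxon_id)")

    @property
    def _pattern(self) -> re.Pattern:
        return re.compile(self.regex)

    def _role_index(self, role: str) -> int | None:
        for i, k in enumerate(self.key):
            if k.split(":", 1)[0] == role:
                return i
        return None

    def obs_info_columns(self) -> list[tuple[int, str]]:
        out = []
        for i, k in enumerate(self.key):
            parts = k.split(":", 1)
            if parts[0] == "obs_info":
                out.append((i, parts[1] if len(parts) > 1 else f"info_{i}"))
        return out

    @classmethod
    def from_config(cls, cfg: dict) -> "ParseSpec":
        return cls(
            regex=cfg["regex"],
            key=tuple(cfg["key"]),
            class_separator=cfg.get("class_separator", ";"),
            rank_separator=cfg.get("rank_separator"),
            reverse_levels=bool(cfg.get("reverse_levels", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ParseSpec":
        import yaml

        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def _lineage_from_match(match: re.Match, spec: ParseSpec) -> list[tuple[str, str | None]]:
    groups = match.groups()
    ci = spec._role_index("class")
    if ci is not None:
        raw = groups[ci]
        levels = []
        for lvl in raw.split(spec.class_separator):
            lvl = lvl.strip()
            if not lvl:
                logger.warning("dropping empty lineage level in %r", raw)
                continue
            if spec.rank_separator and spec.rank_separator in lvl:
                rank, name = lvl.split(spec.rank_separator, 1)
                levels.append((name.strip(), rank.strip() or None))
            else:
                levels.append((lvl, None))
        if spec.reverse_levels:
            levels.reverse()
        return levels
    ni = spec._role_index("taxon_name")
    if ni is not None:
        return [(groups[ni].strip(), None)]
    ti = spec._role_index("taxon_id")
    return [(groups[ti].strip(), None)]


def parse_records(texts, spec: ParseSpec, on_mismatch: str = "error") -> Taxmap:
    """Parse texts into a deduplicated Taxmap (one observation per text).

    Lineage identity is the root-path of level *names*; two records sharing a
    prefix share taxon rows.  When the same path arrives with conflicting
    rank labels the first-seen rank is kept and the conflict logged.

    ``on_mismatch``: ``"error"`` (default) raises on the first text that does
    not match ``spec.regex``; ``"skip"`` drops it with a logged warning.
    """
    if on_mismatch not in ("error", "skip"):
        raise ValueError("on_mismatch must be 'error' or 'skip'")
    pattern = spec._pattern
    info_cols = spec.obs_info_columns()
    tid_role = spec._role_index("taxon_id")

    node_id: dict[tuple[str, ...], str] = {}
    node_rank: dict[str, str | None] = {}
    node_source_id: dict[str, str] = {}
    node_parent: dict[str, str | None] = {}
    node_name: dict[str, str] = {}
    node_order: list[str] = []

    obs_rows: list[dict] = []
    n_skipped = 0

    for i, text in enumerate(texts):
        m = pattern.search(str(text))
        lineage = _lineage_from_match(m, spec) if m else []
        if not lineage:
            if on_mismatch == "error":
                raise TaxmapError(f"input {i} does not match the parse spec: {text!r}")
            n_skipped += 1
            continue
        path: tuple[str, ...] = ()
        parent: str | None = None
        for name, rank in lineage:
            path = path + (name,)
            tid = node_id.get(path)
            if tid is None:
                tid = f"t_{len(node_id) + 1}"
                node_id[path] = tid
                node_rank[tid] = rank
                node_parent[tid] = parent
                node_name[tid] = name
                node_order.append(tid)
            elif rank is not None and node_rank[tid] is not None and node_rank[tid] != rank:
                logger.warning("conflicting rank for %r: keeping %r, ignoring %r",
                               name, node_rank[tid], rank)
            elif node_rank[tid] is None and rank is not None:
                node_rank[tid] = rank
            parent = tid
        leaf = parent
        if tid_role is not None:
            node_source_id[leaf] = m.groups()[tid_role].strip()
        row = {"obs_id": f"o_{len(obs_rows) + 1}", "taxon_id": leaf, "input_index": i}
        for gi, col in info_cols:
            row[col] = m.groups()[gi]
        obs_rows.append(row)

    if n_skipped:
        logger.warning("skipped %d input(s) that did not match the parse spec", n_skipped)

    taxa = pd.DataFrame({
        "taxon_id": node_order,
        "supertaxon_id": [node_parent[t] for t in node_order],
        "name": [node_name[t] for t in node_order],
        "rank": [node_rank[t] for t in node_order],
    })
    if node_source_id:
        taxa["source_taxon_id"] = [node_source_id.get(t) for t in node_order]
    obs = pd.DataFrame(obs_rows) if obs_rows else None
    return Taxmap(taxa, obs)


def parse_fasta(path, spec: ParseSpec, on_mismatch: str = "error") -> Taxmap:
    """Parse a FASTA file: headers through ``spec``, sequences as a column.

    Sequences are uppercased; whitespace, ``*`` and ``-`` are stripped.
    Wrapped sequence lines are joined; duplicate headers are allowed and
    yield distinct observations.
    """
    from Bio import SeqIO

    headers: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        headers.append(rec.description)
        seqs.append(re.sub(r"[\s*\-]", "", str(rec.seq)).upper())
    if not headers:
        raise TaxmapError(f"no FASTA records found in {path}")
    tm = parse_records(headers, spec, on_mismatch=on_mismatch)
    tm.obs["sequence"] = [seqs[i] for i in tm.obs["input_index"]]
    return tm


def write_lineages(tm: Taxmap, class_separator: str = ";",
                   rank_separator: str | None = None) -> list[str]:
    """Render each observation's root-to-taxon lineage as a string.

    The inverse of :func:`parse_records`: parsing the rendered strings with
    the same separators reconstructs an isomorphic Taxmap.  Raises if a
    separator occurs inside a taxon name (the render would be ambiguous).
    """
    names = dict(zip(tm.taxa["taxon_id"], tm.taxa["name"]))
    ranks = dict(zip(tm.taxa["taxon_id"], tm.taxa.get("rank", [None] * len(tm.taxa))))
    paths = tm.supertaxa(recursive=True, include_input=True)

    def render_level(tid: str) -> str:
        name = str(names[tid])
        rank = ranks.get(tid)
        rank = None if rank is None or (isinstance(rank, float)) or pd.isna(rank) else str(rank)
        for sep in filter(None, (class_separator, rank_separator)):
            if sep in name or (rank and sep in rank):
                raise TaxmapError(
                    f"separator {sep!r} occurs inside taxon {tid!r} ({name!r}); render is ambiguous"
                )
        if rank_separator and rank:
            return f"{rank}{rank_separator}{name}"
        return name

    out = []
    for tid in tm.obs["taxon_id"]:
        path = list(reversed(paths[tid]))  # root-most first
        out.append(class_separator.join(render_level(t) for t in path))
    return out
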