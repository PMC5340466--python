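"""The taxmap data object.

A :class:`Taxmap` stores a taxonomic hierarchy as an *edge list* of unique
taxon IDs (each row names its supertaxon, ``None`` for roots) together with a
table of *observations* (sequences, OTUs, votes, GO terms ...) each assigned
to exactly one taxon.  The only assumption made about the user's data is that
it can be represented as observations attached to a forest.

Derived per-taxon attributes such as the number of observations in a subtree
are registered as *computed columns*: functions evaluated on every access so
they can never go stale after filtering or sampling.
"""
from __future__ import annotations

import logging
from collections import deque
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("taxomap")

TAXON_PROTECTED = ("taxon_id", "supertaxon_id")
OBS_PROTECTED = ("obs_id", "taxon_id")

#: sentinel written to TSV files for a missing supertaxon (root rows)
NA_TOKEN = "NA"


class TaxmapError(ValueError):
    """Structural problem in a taxmap (broken forest or referential integrity)."""


def _clean_parent(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if value is pd.NA or value is pd.NaT:
        return None
    return str(value)


def _n_obs(tm: "Taxmap") -> np.ndarray:
    """Observations assigned to each taxon or any of its subtaxa."""
    counts = tm._subtree_obs_counts()
    return counts


def _n_obs_direct(tm: "Taxmap") -> np.ndarray:
    direct = tm._index().direct_obs
    return np.array([len(direct[t]) for t in tm.taxon_ids], dtype=np.int64)


def _n_subtaxa(tm: "Taxmap") -> np.ndarray:
    sub = tm.subtaxa(recursive=True)
    return np.array([len(sub[t]) for t in tm.taxon_ids], dtype=np.int64)


DEFAULT_TAXON_FUNCS: dict[str, Callable[["Taxmap"], np.ndarray]] = {
    "n_obs": _n_obs,
    "n_obs_direct": _n_obs_direct,
    "n_subtaxa": _n_subtaxa,
}


class _Index:
    """Lazily built adjacency index over the two tables (internal)."""

    __slots__ = ("parent", "children", "row_pos", "direct_obs", "obs_pos")

    def __init__(self, tm: "Taxmap"):
        ids = tm.taxa["taxon_id"].tolist()
        parents = [_clean_parent(p) for p in tm.taxa["supertaxon_id"].tolist()]
        self.parent = dict(zip(ids, parents))
        self.children: dict[str, list[str]] = {t: [] for t in ids}
        for t, p in zip(ids, parents):
            if p is not None:
                if p not in self.children:
                    raise TaxmapError(f"supertaxon_id {p!r} of taxon {t!r} is not a taxon_id")
                self.children[p].append(t)
        self.row_pos = {t: k for k, t in enumerate(ids)}
        self.direct_obs: dict[str, list[str]] = {t: [] for t in ids}
        self.obs_pos: dict[str, int] = {}
        for k, (oid, t) in enumerate(zip(tm.obs["obs_id"], tm.obs["taxon_id"])):
            if t not in self.direct_obs:
                raise TaxmapError(f"observation {oid!r} maps to unknown taxon {t!r}")
            self.direct_obs[t].append(oid)
            self.obs_pos[oid] = k


class Taxmap:
    """Taxonomic forest (edge list) + observation table + computed columns.

    Parameters
    ----------
    taxa:
        DataFrame with at least ``taxon_id`` and ``supertaxon_id`` columns;
        ``supertaxon_id`` is ``None``/NaN for roots.  Arbitrary extra columns
        (``name``, ``rank``, ...) are carried along untouched.
    obs:
        DataFrame with at least ``obs_id`` and ``taxon_id``; one row per
        observation, each mapped to exactly one taxon.
    taxon_funcs / obs_funcs:
        Registries of computed columns, ``name -> f(taxmap) -> column``.
        Re-evaluated on every access, never persisted.
    """

    def __init__(
        self,
        taxa: pd.DataFrame,
        obs: pd.DataFrame | None = None,
        taxon_funcs: Mapping[str, Callable] | None = None,
        obs_funcs: Mapping[str, Callable] | None = None,
        validate: bool = True,
    ):
        taxa = taxa.reset_index(drop=True).copy()
        if "supertaxon_id" not in taxa.columns and "taxon_id" in taxa.columns:
            taxa["supertaxon_id"] = None
        if obs is None:
            obs = pd.DataFrame({"obs_id": pd.Series(dtype=str), "taxon_id": pd.Series(dtype=str)})
        obs = obs.reset_index(drop=True).copy()
        taxa["taxon_id"] = taxa["taxon_id"].astype(str)
        taxa["supertaxon_id"] = [_clean_parent(p) for p in taxa["supertaxon_id"]]
        taxa["supertaxon_id"] = taxa["supertaxon_id"].astype(object)
        if len(obs):
            obs["obs_id"] = obs["obs_id"].astype(str)
            obs["taxon_id"] = obs["taxon_id"].astype(str)
        self.taxa = taxa
        self.obs = obs
        self.taxon_funcs = dict(DEFAULT_TAXON_FUNCS if taxon_funcs is None else taxon_funcs)
        self.obs_funcs = dict(obs_funcs or {})
        self._idx: _Index | None = None
        if validate:
            self.validate()

    # ------------------------------------------------------------------ basics
    @property
    def taxon_ids(self) -> list[str]:
        return self.taxa["taxon_id"].tolist()

    @property
    def obs_ids(self) -> list[str]:
        return self.obs["obs_id"].tolist()

    def __len__(self) -> int:
        return len(self.taxa)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Taxmap: {len(self.taxa)} taxa ({len(self.roots())} roots), "
            f"{len(self.obs)} observations>"
        )

    def _index(self) -> _Index:
        if self._idx is None:
            self._idx = _Index(self)
        return self._idx

    def _replace(self, taxa: pd.DataFrame | None = None, obs: pd.DataFrame | None = None,
                 validate: bool = True) -> "Taxmap":
        return Taxmap(
            self.taxa if taxa is None else taxa,
            self.obs if obs is None else obs,
            taxon_funcs=self.taxon_funcs,
            obs_funcs=self.obs_funcs,
            validate=validate,
        )

    def copy(self) -> "Taxmap":
        return self._replace(validate=False)

    # -------------------------------------------------------------- validation
    def validate(self) -> "Taxmap":
        """Check forest + referential-integrity invariants; raise TaxmapError."""
        ids = self.taxa["taxon_id"]
        if (ids == "").any():
            raise TaxmapError("empty taxon_id")
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise TaxmapError(f"duplicate taxon_id {dup!r}")
        if len(self.obs):
            if self.obs["obs_id"].duplicated().any():
                dup = self.obs["obs_id"][self.obs["obs_id"].duplicated()].iloc[0]
                raise TaxmapError(f"duplicate obs_id {dup!r}")
        self._idx = None
        idx = self._index()  # raises on dangling parent / obs references
        # acyclicity: every node must be reachable from a root via child edges
        seen: set[str] = set()
        stack = [t for t, p in idx.parent.items() if p is None]
        while stack:
            t = stack.pop()
            seen.add(t)
            stack.extend(idx.children[t])
        if len(seen) != len(self.taxa):
            lost = next(t for t in self.taxon_ids if t not in seen)
            raise TaxmapError(f"cycle in supertaxon relation (taxon {lost!r} unreachable from any root)")
        return self

    def _require_ids(self, ids: Iterable[str] | None) -> list[str]:
        idx = self._index()
        if ids is None:
            return self.taxon_ids
        ids = [ids] if isinstance(ids, str) else list(ids)
        for t in ids:
            if t not in idx.row_pos:
                raise KeyError(f"unknown taxon_id: {t!r}")
        return ids

    # -------------------------------------------------------------- traversals
    def roots(self) -> list[str]:
        """Taxa with no supertaxon, in taxon-table row order."""
        idx = self._index()
        return [t for t in self.taxon_ids if idx.parent[t] is None]

    def subtaxa(self, ids: Iterable[str] | None = None, recursive: bool = True,
                include_input: bool = False) -> dict[str, list[str]]:
        """Descendants of each queried taxon, in taxon-table row order.

        ``recursive=False`` returns direct children only; ``include_input``
        adds the queried taxon itself.
        """
        idx = self._index()
        ids = self._require_ids(ids)
        out: dict[str, list[str]] = {}
        for t in ids:
            if recursive:
                acc: list[str] = []
                stack = list(reversed(idx.children[t]))
                while stack:
                    c = stack.pop()
                    acc.append(c)
                    stack.extend(reversed(idx.children[c]))
            else:
                acc = list(idx.children[t])
            if include_input:
                acc.append(t)
            acc.sort(key=idx.row_pos.__getitem__)
            out[t] = acc
        return out

    def supertaxa(self, ids: Iterable[str] | None = None, recursive: bool = True,
                  include_input: bool = False) -> dict[str, list[str]]:
        """Ancestors of each queried taxon, nearest first."""
        idx = self._index()
        ids = self._require_ids(ids)
        out: dict[str, list[str]] = {}
        for t in ids:
            acc = [t] if include_input else []
            p = idx.parent[t]
            while p is not None:
                acc.append(p)
                if not recursive:
                    break
                p = idx.parent[p]
            out[t] = acc
        return out

    def observations(self, ids: Iterable[str] | None = None,
                     recursive: bool = True) -> dict[str, list[str]]:
        """obs_ids assigned to each queried taxon (or its subtree), obs-table row order."""
        idx = self._index()
        ids = self._require_ids(ids)
        out: dict[str, list[str]] = {}
        for t in ids:
            if recursive:
                acc = list(idx.direct_obs[t])
                stack = list(idx.children[t])
                while stack:
                    c = stack.pop()
                    acc.extend(idx.direct_obs[c])
                    stack.extend(idx.children[c])
                acc.sort(key=idx.obs_pos.__getitem__)
            else:
                acc = list(idx.direct_obs[t])
            out[t] = acc
        return out

    def _topo_order(self) -> list[str]:
        """Taxon ids, parents before children."""
        idx = self._index()
        order: list[str] = []
        dq = deque(t for t in self.taxon_ids if idx.parent[t] is None)
        while dq:
            t = dq.popleft()
            order.append(t)
            dq.extend(idx.children[t])
        return order

    def _subtree_obs_counts(self) -> np.ndarray:
        idx = self._index()
        counts = {t: len(idx.direct_obs[t]) for t in self.taxon_ids}
        for t in reversed(self._topo_order()):
            p = idx.parent[t]
            if p is not None:
                counts[p] += counts[t]
        return np.array([counts[t] for t in self.taxon_ids], dtype=np.int64)

    def n_obs(self) -> pd.Series:
        """Computed column: observation count per taxon, subtaxa included."""
        return pd.Series(self._subtree_obs_counts(), index=self.taxa.index, name="n_obs")

    # ------------------------------------------------------- computed columns
    def register_taxon_func(self, name: str, fn: Callable[["Taxmap"], Sequence]) -> None:
        self.taxon_funcs[name] = fn

    def register_obs_func(self, name: str, fn: Callable[["Taxmap"], Sequence]) -> None:
        self.obs_funcs[name] = fn

    def _augmented(self, table: pd.DataFrame, funcs: Mapping[str, Callable]) -> pd.DataFrame:
        frame = table.copy()
        for name, fn in funcs.items():
            if name in frame.columns:
                # user columns shadow computed columns
                logger.warning("column %r shadows a computed column of the same name", name)
                continue
            frame[name] = np.asarray(fn(self))
        return frame

    def taxa_table(self) -> pd.DataFrame:
        """Taxon table with all computed columns materialized (a temporary view)."""
        return self._augmented(self.taxa, self.taxon_funcs)

    def obs_table(self) -> pd.DataFrame:
        """Observation table with all computed columns materialized."""
        return self._augmented(self.obs, self.obs_funcs)

    # ------------------------------------------------------------ serialization
    def to_dir(self, path) -> None:
        """Write ``taxa.tsv`` and ``observations.tsv``; root supertaxon as ``NA``."""
        import os

        os.makedirs(path, exist_ok=True)
        self.taxa.to_csv(os.path.join(path, "taxa.tsv"), sep="\t", index=False, na_rep=NA_TOKEN)
        self.obs.to_csv(os.path.join(path, "observations.tsv"), sep="\t", index=False,
                        na_rep=NA_TOKEN)

    @classmethod
    def from_dir(cls, path) -> "Taxmap":
        import os

        taxa = _read_tsv(os.path.join(path, "taxa.tsv"))
        obs = _read_tsv(os.path.join(path, "observations.tsv"))
        taxa["supertaxon_id"] = [None if v == NA_TOKEN else v for v in taxa["supertaxon_id"]]
        return cls(taxa, obs)

    def to_newick(self) -> list[str]:
        """One newick string per root; node labels are taxon names, no branch lengths."""
        idx = self._index()
        names = dict(zip(self.taxa["taxon_id"], self.taxa.get("name", self.taxa["taxon_id"])))

        def label(t: str) -> str:
            s = str(names[t])
            if any(c in s for c in " ():;,[]'\t\n"):
                return "'" + s.replace("'", "''") + "'"
            return s

        def render(t: str) -> str:
            kids = idx.children[t]
            if not kids:
                return label(t)
            return "(" + ",".join(render(c) for c in kids) + ")" + label(t)

        return [render(r) + ";" for r in self.roots()]


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    for col in df.columns:
        if col in TAXON_PROTECTED or col in OBS_PROTECTED:
            continue
        vals = df[col]
        try:
            num = pd.to_numeric(vals)
        except (ValueError, TypeError):
            if set(vals.unique()) <= {"True", "False"}:
                df[col] = vals == "True"
            continue
        df[col] = num
    return df


# ------------------------------------------------------------- functional API
def roots(tm: Taxmap) -> list[str]:
    return tm.roots()


def subtaxa(tm: Taxmap, ids=None, recursive: bool = True, include_input: bool = False):
    return tm.subtaxa(ids, recursive=recursive, include_input=include_input)


def supertaxa(tm: Taxmap, ids=None, recursive: bool = True, include_input: bool = False):
    return tm.supertaxa(ids, recursive=recursive, include_input=include_input)


def observations(tm: Taxmap, ids=None, recursive: bool = True):
    return tm.observations(ids, recursive=recursive)


def n_obs(tm: Taxmap) -> pd.Series:
    return tm.n_obs()
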