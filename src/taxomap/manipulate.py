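"""Hierarchy-aware table verbs for Taxmap objects.

Filtering a taxonomy is harder than filtering a flat table: removing a taxon
raises questions about its subtaxa, supertaxa and observations.  Each verb
here makes those choices explicit through flags, and every verb returns a new
valid Taxmap (inputs are never mutated).

Predicates may be a string expression over table columns (user or computed,
evaluated with ``DataFrame.eval``), a callable receiving the augmented table,
or a boolean mask.
"""
from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import OBS_PROTECTED, TAXON_PROTECTED, Taxmap, TaxmapError


def _eval_predicate(frame: pd.DataFrame, pred, what: str) -> np.ndarray:
    if callable(pred):
        mask = pred(frame)
    elif isinstance(pred, str):
        try:
            mask = frame.eval(pred)
        except pd.errors.UndefinedVariableError as exc:
            raise TaxmapError(f"unknown column in {what} predicate: {exc}") from None
    else:
        mask = pred
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if mask.shape != (len(frame),):
        raise TaxmapError(f"{what} predicate produced shape {mask.shape}, expected ({len(frame)},)")
    return mask


def _nearest_survivor(tid: str, parent: dict, keep: set) -> str | None:
    p = parent[tid]
    while p is not None and p not in keep:
        p = parent[p]
    return p


def _apply_taxon_selection(tm: Taxmap, selected: Sequence[str], *, keep_subtaxa: bool = False,
                           keep_supertaxa: bool = False, reassign_obs: bool = True,
                           reassign_taxa: bool = True, invert: bool = False) -> Taxmap:
    """Shared structural core of filter_taxa and sample_n_taxa."""
    idx = tm._index()
    keep = set(selected)
    if keep_subtaxa:
        sub = tm.subtaxa(list(keep), recursive=True)
        for vals in sub.values():
            keep.update(vals)
    if keep_supertaxa:
        sup = tm.supertaxa(list(keep), recursive=True)
        for vals in sup.values():
            keep.update(vals)
    if invert:
        keep = set(tm.taxon_ids) - keep

    taxa = tm.taxa[tm.taxa["taxon_id"].isin(keep)].copy()
    new_parent = []
    for tid, p in zip(taxa["taxon_id"], taxa["supertaxon_id"]):
        if p is None or p in keep:
            new_parent.append(p)
        elif reassign_taxa:
            new_parent.append(_nearest_survivor(tid, idx.parent, keep))
        else:
            new_parent.append(None)  # orphaned survivor becomes a root
    taxa["supertaxon_id"] = pd.Series(new_parent, index=taxa.index, dtype=object)

    obs = tm.obs
    if len(obs):
        new_taxon = []
        keep_obs = []
        for t in obs["taxon_id"]:
            if t in keep:
                new_taxon.append(t)
                keep_obs.append(True)
            elif reassign_obs:
                anc = _nearest_survivor(t, idx.parent, keep)
                new_taxon.append(anc)
                keep_obs.append(anc is not None)
            else:
                new_taxon.append(None)
                keep_obs.append(False)
        obs = obs.copy()
        obs["taxon_id"] = pd.Series(new_taxon, index=obs.index, dtype=object)
        obs = obs[np.asarray(keep_obs)]
    return tm._replace(taxa=taxa, obs=obs)


def filter_taxa(tm: Taxmap, pred, *, keep_subtaxa: bool = False, keep_supertaxa: bool = False,
                reassign_obs: bool = True, reassign_taxa: bool = True,
                invert: bool = False) -> Taxmap:
    """Keep taxa passing ``pred``; control the fate of relatives and observations.

    ``keep_subtaxa``/``keep_supertaxa`` extend the selection to descendants /
    ancestors of passing taxa; ``invert`` complements the selection *after*
    that expansion.  Surviving taxa whose parent was removed are re-parented
    to their nearest surviving ancestor when ``reassign_taxa`` (else they
    become roots).  Observations of removed taxa move to their nearest
    surviving ancestor when ``reassign_obs``, else they are dropped.
    """
    mask = _eval_predicate(tm.taxa_table(), pred, "taxon")
    selected = [t for t, m in zip(tm.taxon_ids, mask) if m]
    return _apply_taxon_selection(
        tm, selected, keep_subtaxa=keep_subtaxa, keep_supertaxa=keep_supertaxa,
        reassign_obs=reassign_obs, reassign_taxa=reassign_taxa, invert=invert)


def filter_obs(tm: Taxmap, pred, *, drop_empty_taxa: bool = False) -> Taxmap:
    """Keep observations passing ``pred``; optionally prune taxa left empty.

    With ``drop_empty_taxa`` every taxon whose subtree holds no surviving
    observation is removed (such taxa form whole subtrees, so no re-parenting
    is ever needed).
    """
    mask = _eval_predicate(tm.obs_table(), pred, "observation")
    out = tm._replace(obs=tm.obs[mask])
    if drop_empty_taxa:
        out = filter_taxa(out, out.n_obs().to_numpy() > 0)
    return out


def _new_columns(tm: Taxmap, table: pd.DataFrame, augmented: pd.DataFrame,
                 new_columns: dict, protected: tuple, what: str) -> pd.DataFrame:
    result = table.copy()
    for name, expr in new_columns.items():
        if name in protected:
            raise TaxmapError(f"cannot overwrite protected column {name!r}")
        if callable(expr):
            values = expr(augmented)
        elif isinstance(expr, str):
            try:
                values = augmented.eval(expr)
            except pd.errors.UndefinedVariableError as exc:
                raise TaxmapError(f"unknown column in {what} expression: {exc}") from None
        else:
            values = expr
        values = np.asarray(values) if not np.isscalar(values) else np.repeat(values, len(table))
        result[name] = values
        augmented = augmented.assign(**{name: values})  # later exprs may reference earlier ones
    return result


def mutate_taxa(tm: Taxmap, **new_columns) -> Taxmap:
    """Add (or replace non-protected) columns on the taxon table."""
    taxa = _new_columns(tm, tm.taxa, tm.taxa_table(), new_columns, TAXON_PROTECTED, "taxon")
    return tm._replace(taxa=taxa)


def mutate_obs(tm: Taxmap, **new_columns) -> Taxmap:
    """Add (or replace non-protected) columns on the observation table."""
    obs = _new_columns(tm, tm.obs, tm.obs_table(), new_columns, OBS_PROTECTED, "observation")
    return tm._replace(obs=obs)


def transmute_taxa(tm: Taxmap, **new_columns) -> Taxmap:
    """Like mutate_taxa but keep only taxon_id/supertaxon_id plus the new columns."""
    taxa = _new_columns(tm, tm.taxa, tm.taxa_table(), new_columns, TAXON_PROTECTED, "taxon")
    return tm._replace(taxa=taxa[list(TAXON_PROTECTED) + list(new_columns)])


def transmute_obs(tm: Taxmap, **new_columns) -> Taxmap:
    """Like mutate_obs but keep only obs_id/taxon_id plus the new columns."""
    obs = _new_columns(tm, tm.obs, tm.obs_table(), new_columns, OBS_PROTECTED, "observation")
    return tm._replace(obs=obs[list(OBS_PROTECTED) + list(new_columns)])


def _select(table: pd.DataFrame, columns: Iterable[str], protected: tuple) -> pd.DataFrame:
    columns = list(columns)
    for c in columns:
        if c not in table.columns:
            raise TaxmapError(f"unknown column: {c!r}")
    keep = list(protected) + [c for c in columns if c not in protected]
    return table[keep]


def select_taxa(tm: Taxmap, columns: Iterable[str]) -> Taxmap:
    """Subset taxon-table columns; taxon_id and supertaxon_id are always kept."""
    return tm._replace(taxa=_select(tm.taxa, columns, TAXON_PROTECTED))


def select_obs(tm: Taxmap, columns: Iterable[str]) -> Taxmap:
    """Subset observation-table columns; obs_id and taxon_id are always kept."""
    return tm._replace(obs=_select(tm.obs, columns, OBS_PROTECTED))


def arrange_taxa(tm: Taxmap, by, ascending: bool = True) -> Taxmap:
    """Reorder taxon rows (stable sort); traversal *sets* are unaffected."""
    frame = tm.taxa_table()
    by = [by] if isinstance(by, str) else list(by)
    for c in by:
        if c not in frame.columns:
            raise TaxmapError(f"unknown column: {c!r}")
    order = frame.sort_values(by, ascending=ascending, kind="stable").index
    return tm._replace(taxa=tm.taxa.loc[order])


def arrange_obs(tm: Taxmap, by, ascending: bool = True) -> Taxmap:
    """Reorder observation rows (stable sort)."""
    frame = tm.obs_table()
    by = [by] if isinstance(by, str) else list(by)
    for c in by:
        if c not in frame.columns:
            raise TaxmapError(f"unknown column: {c!r}")
    order = frame.sort_values(by, ascending=ascending, kind="stable").index
    return tm._replace(obs=tm.obs.loc[order])


# ------------------------------------------------------------------- sampling
def weighted_sample_without_replacement(weights, n: int, rng: np.random.Generator) -> list[int]:
    """Sequential weighted draws: each draw proportional to remaining weights.

    This is the distribution all sampling verbs use; exposed so its marginals
    can be checked directly against enumeration.
    """
    w = np.asarray(weights, dtype=float).copy()
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise TaxmapError("weights must be finite and non-negative")
    if n > np.count_nonzero(w):
        raise TaxmapError(f"cannot draw {n} items from {np.count_nonzero(w)} with positive weight")
    picks = []
    for _ in range(n):
        p = w / w.sum()
        k = int(rng.choice(len(w), p=p))
        picks.append(k)
        w[k] = 0.0
    return picks


def sample_n_taxa(tm: Taxmap, n: int, weights=None, seed: int = 0, **filter_flags) -> Taxmap:
    """Randomly keep ``n`` taxa (weighted, without replacement), then apply
    the filter_taxa flag set to the selection.  Deterministic given ``seed``."""
    if n > len(tm.taxa):
        raise TaxmapError(f"cannot sample {n} taxa from {len(tm.taxa)}")
    w = np.ones(len(tm.taxa)) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    picks = weighted_sample_without_replacement(w, n, rng)
    selected = [tm.taxon_ids[k] for k in sorted(picks)]
    return _apply_taxon_selection(tm, selected, **filter_flags)


def sample_n_obs(tm: Taxmap, n: int, weights=None, seed: int = 0,
                 drop_empty_taxa: bool = False) -> Taxmap:
    """Randomly keep ``n`` observations (weighted, without replacement)."""
    if n > len(tm.obs):
        raise TaxmapError(f"cannot sample {n} observations from {len(tm.obs)}")
    w = np.ones(len(tm.obs)) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    picks = weighted_sample_without_replacement(w, n, rng)
    mask = np.zeros(len(tm.obs), dtype=bool)
    mask[picks] = True
    return filter_obs(tm, mask, drop_empty_taxa=drop_empty_taxa)


def taxonomic_sample(tm: Taxmap, rank: str, min_counts: int = 0,
                     max_counts: int = 2**31, seed: int = 0) -> Taxmap:
    """Even out observation counts across all taxa of one rank.

    Rank-level taxa whose subtree carries fewer than ``min_counts``
    observations are removed with their whole subtree (observations dropped,
    not reassigned); those with more than ``max_counts`` have their subtree
    observations uniformly subsampled down to exactly ``max_counts``.
    Observations not under any taxon of the given rank are untouched.
    """
    ranks = tm.taxa.get("rank")
    if ranks is None:
        raise TaxmapError("taxon table has no 'rank' column")
    at_rank = [t for t, r in zip(tm.taxon_ids, ranks) if r == rank]
    if not at_rank:
        avail = sorted({str(r) for r in ranks.dropna().unique()})
        raise TaxmapError(f"no taxa at rank {rank!r}; available ranks: {avail}")

    rng = np.random.default_rng(seed)
    obs_of = tm.observations(at_rank, recursive=True)
    drop_taxa: set[str] = set()
    drop_obs: set[str] = set()
    sub = tm.subtaxa(at_rank, recursive=True, include_input=True)
    for t in at_rank:
        c = len(obs_of[t])
        if c < min_counts:
            drop_taxa.update(sub[t])
            drop_obs.update(obs_of[t])
        elif c > max_counts:
            picks = rng.choice(c, size=max_counts, replace=False)
            keep = {obs_of[t][k] for k in picks}
            drop_obs.update(o for o in obs_of[t] if o not in keep)

    obs = tm.obs[~tm.obs["obs_id"].isin(drop_obs)]
    out = tm._replace(obs=obs)
    if drop_taxa:
        out = _apply_taxon_selection(out, [t for t in out.taxon_ids if t not in drop_taxa],
                                     reassign_obs=False, reassign_taxa=True)
    return out
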