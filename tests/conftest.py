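"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately work on the raw taxon/observation
DataFrames with plain dict/BFS graph code, never through the Taxmap
traversal implementation they are used to check.
"""
from __future__ import annotations

import pandas as pd
import pytest

from taxomap import FixtureConfig, Taxmap, random_taxmap


def make_taxmap(edges, obs=None, ranks=None):
    """Build a Taxmap from [(taxon_id, parent_or_None), ...] and [(obs_id, taxon_id), ...]."""
    taxa = pd.DataFrame({
        "taxon_id": [e[0] for e in edges],
        "supertaxon_id": [e[1] for e in edges],
        "name": [e[0] for e in edges],
    })
    if ranks is not None:
        taxa["rank"] = ranks
    obs_df = None
    if obs:
        obs_df = pd.DataFrame({"obs_id": [o[0] for o in obs], "taxon_id": [o[1] for o in obs]})
    return Taxmap(taxa, obs_df)


@pytest.fixture
def chain_tm():
    """A -> B -> C with one observation on C."""
    return make_taxmap([("A", None), ("B", "A"), ("C", "B")], [("o1", "C")])


@pytest.fixture
def forest_factory():
    def make(seed, n_taxa=50, n_obs=100, n_roots=1, max_depth=5):
        cfg = FixtureConfig(n_taxa=n_taxa, n_obs=n_obs, n_roots=n_roots,
                            max_depth=max_depth, seed=seed)
        return random_taxmap(cfg).taxmap
    return make


# ----------------------------------------------------------- graph oracles
def adjacency(tm):
    ids = tm.taxa["taxon_id"].tolist()
    parent = {t: p for t, p in zip(ids, tm.taxa["supertaxon_id"])}
    children = {t: [] for t in ids}
    for t in ids:
        p = parent[t]
        if p is not None:
            children[p].append(t)
    return ids, parent, children


def oracle_roots(tm):
    ids, parent, _ = adjacency(tm)
    return [t for t in ids if parent[t] is None]


def oracle_subtaxa(tm, tid, recursive=True, include_input=False):
    ids, _, children = adjacency(tm)
    if recursive:
        found, queue = set(), list(children[tid])
        while queue:
            c = queue.pop(0)
            found.add(c)
            queue.extend(children[c])
    else:
        found = set(children[tid])
    if include_input:
        found.add(tid)
    return [t for t in ids if t in found]


def oracle_supertaxa(tm, tid, recursive=True, include_input=False):
    _, parent, _ = adjacency(tm)
    out = [tid] if include_input else []
    p = parent[tid]
    while p is not None:
        out.append(p)
        if not recursive:
            break
        p = parent[p]
    return out


def oracle_observations(tm, tid, recursive=True):
    subtree = set(oracle_subtaxa(tm, tid, recursive=True, include_input=True)) \
        if recursive else {tid}
    return [o for o, t in zip(tm.obs["obs_id"], tm.obs["taxon_id"]) if t in subtree]


def oracle_filter(tm, selected, keep_subtaxa=False, keep_supertaxa=False,
                  reassign_obs=True, reassign_taxa=True, invert=False):
    """Independent set-based model of filter_taxa; returns (taxa_rows, obs_rows).

    taxa_rows: [(taxon_id, new_parent)], obs_rows: [(obs_id, new_taxon)].
    """
    ids, parent, children = adjacency(tm)
    keep = set(selected)
    if keep_subtaxa:
        for t in list(keep):
            keep.update(oracle_subtaxa(tm, t, recursive=True))
    if keep_supertaxa:
        for t in list(keep):
            keep.update(oracle_supertaxa(tm, t, recursive=True))
    if invert:
        keep = set(ids) - keep

    def nearest_kept_ancestor(t):
        p = parent[t]
        while p is not None and p not in keep:
            p = parent[p]
        return p

    taxa_rows = []
    for t in ids:
        if t not in keep:
            continue
        p = parent[t]
        if p is not None and p not in keep:
            p = nearest_kept_ancestor(t) if reassign_taxa else None
        taxa_rows.append((t, p))
    obs_rows = []
    for o, t in zip(tm.obs["obs_id"], tm.obs["taxon_id"]):
        if t in keep:
            obs_rows.append((o, t))
        elif reassign_obs:
            anc = nearest_kept_ancestor(t)
            if anc is not None:
                obs_rows.append((o, anc))
    return taxa_rows, obs_rows
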