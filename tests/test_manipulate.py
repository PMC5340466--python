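"""Hierarchy-aware verbs: filter/select/mutate/arrange/sample semantics."""
import itertools

import numpy as np
import pandas as pd
import pytest

import taxomap.manipulate as man
from taxomap import FixtureConfig, Taxmap, TaxmapError, random_taxmap

from conftest import make_taxmap, oracle_filter


def assert_matches_oracle(out, taxa_rows, obs_rows):
    assert list(zip(out.taxa["taxon_id"], out.taxa["supertaxon_id"])) == taxa_rows
    assert sorted(zip(out.obs["obs_id"], out.obs["taxon_id"])) == sorted(obs_rows)


class TestFilterTaxa:
    def test_always_true_is_identity(self, forest_factory):
        tm = forest_factory(1, n_taxa=30, n_obs=40)
        out = man.filter_taxa(tm, np.ones(30, dtype=bool))
        pd.testing.assert_frame_equal(out.taxa, tm.taxa)
        pd.testing.assert_frame_equal(out.obs, tm.obs)

    def test_obs_reassigned_to_nearest_survivor(self, chain_tm):
        out = man.filter_taxa(chain_tm, [True, True, False], reassign_obs=True)
        assert out.taxon_ids == ["A", "B"]
        assert out.obs["taxon_id"].tolist() == ["B"]

    def test_obs_dropped_without_reassignment(self, chain_tm):
        out = man.filter_taxa(chain_tm, [True, True, False], reassign_obs=False)
        assert out.taxon_ids == ["A", "B"]
        assert len(out.obs) == 0

    def test_keep_subtaxa_preserves_whole_clade(self, chain_tm):
        out = man.filter_taxa(chain_tm, [False, True, False], keep_subtaxa=True)
        assert out.taxon_ids == ["B", "C"]
        assert out.taxa["supertaxon_id"].tolist() == [None, "B"]

    def test_keep_supertaxa_preserves_ancestry(self, chain_tm):
        out = man.filter_taxa(chain_tm, [False, False, True], keep_supertaxa=True)
        assert out.taxon_ids == ["A", "B", "C"]

    def test_string_predicate_over_computed_column(self, chain_tm):
        out = man.filter_taxa(chain_tm, "n_obs >= 1")
        assert out.taxon_ids == ["A", "B", "C"]

    def test_unknown_column_named_in_error(self, chain_tm):
        with pytest.raises(TaxmapError, match="bogus"):
            man.filter_taxa(chain_tm, "bogus > 1")

    def test_invert_applies_after_expansion(self, chain_tm):
        out = man.filter_taxa(chain_tm, [False, True, False], keep_subtaxa=True,
                              invert=True, reassign_obs=False)
        assert out.taxon_ids == ["A"]

    def test_invert_twice_restores_selection(self, forest_factory):
        tm = forest_factory(2, n_taxa=30, n_obs=30)
        sel = np.arange(30) % 2 == 0
        once = man.filter_taxa(tm, sel, invert=True)
        complement = np.array([t in set(once.taxon_ids) for t in tm.taxon_ids])
        twice = man.filter_taxa(tm, complement, invert=True)
        assert twice.taxon_ids == man.filter_taxa(tm, sel).taxon_ids

    @pytest.mark.parametrize("flags", list(itertools.product([False, True], repeat=4)))
    def test_all_flag_combinations_match_set_oracle(self, forest_factory, flags):
        keep_sub, keep_sup, reassign_obs, invert = flags
        for seed in range(12):
            tm = forest_factory(seed * 31 + 5, n_taxa=8 + seed * 11 % 40, n_obs=40)
            rng = np.random.default_rng(seed)
            sel_mask = rng.random(len(tm.taxa)) < 0.4
            selected = [t for t, m in zip(tm.taxon_ids, sel_mask) if m]
            for reassign_taxa in (True, False):
                out = man.filter_taxa(tm, sel_mask, keep_subtaxa=keep_sub,
                                      keep_supertaxa=keep_sup, reassign_obs=reassign_obs,
                                      reassign_taxa=reassign_taxa, invert=invert)
                out.validate()
                taxa_rows, obs_rows = oracle_filter(
                    tm, selected, keep_subtaxa=keep_sub, keep_supertaxa=keep_sup,
                    reassign_obs=reassign_obs, reassign_taxa=reassign_taxa, invert=invert)
                assert_matches_oracle(out, taxa_rows, obs_rows)


class TestFilterObs:
    def test_all_false_with_drop_empty_empties_taxmap(self, chain_tm):
        out = man.filter_obs(chain_tm, [False], drop_empty_taxa=True)
        assert len(out.taxa) == 0 and len(out.obs) == 0

    def test_taxa_untouched_when_one_obs_remains(self):
        tm = make_taxmap([("A", None)], [("o1", "A"), ("o2", "A")])
        out = man.filter_obs(tm, lambda df: df["obs_id"] == "o1", drop_empty_taxa=True)
        assert out.taxon_ids == ["A"] and out.obs_ids == ["o1"]

    @pytest.mark.parametrize("seed", range(8))
    def test_drop_empty_taxa_postcondition(self, forest_factory, seed):
        tm = forest_factory(seed + 50, n_taxa=40, n_obs=60)
        rng = np.random.default_rng(seed)
        keep = rng.random(len(tm.obs)) < 0.3
        out = man.filter_obs(tm, keep, drop_empty_taxa=True)
        out.validate()
        assert (out.n_obs() > 0).all()
        assert sorted(out.obs_ids) == sorted(o for o, k in zip(tm.obs_ids, keep) if k)


class TestMutateSelectArrange:
    def test_mutate_constant_column(self, chain_tm):
        out = man.mutate_taxa(chain_tm, one=1)
        assert out.taxa["one"].tolist() == [1, 1, 1]
        pd.testing.assert_frame_equal(out.taxa.drop(columns="one"), chain_tm.taxa)

    def test_mutate_expression_over_computed(self, forest_factory):
        tm = forest_factory(4, n_taxa=25, n_obs=50)
        out = man.mutate_taxa(tm, x="n_obs * 2")
        assert out.taxa["x"].tolist() == (tm.n_obs() * 2).tolist()

    def test_mutate_protected_column_rejected(self, chain_tm):
        with pytest.raises(TaxmapError, match="protected"):
            man.mutate_taxa(chain_tm, taxon_id="1")

    def test_transmute_obs_keeps_only_ids_and_new(self):
        tm = make_taxmap([("A", None)], [("o1", "A")])
        tm.obs["sequence"] = ["ACGTA"]
        out = man.transmute_obs(tm, seq_len=lambda df: df["sequence"].str.len())
        assert list(out.obs.columns) == ["obs_id", "taxon_id", "seq_len"]
        assert out.obs["seq_len"].tolist() == [5]

    def test_select_obs_empty_keeps_protected(self, chain_tm):
        out = man.select_obs(chain_tm, [])
        assert list(out.obs.columns) == ["obs_id", "taxon_id"]

    def test_select_unknown_column_errors(self, chain_tm):
        with pytest.raises(TaxmapError, match="ghost"):
            man.select_taxa(chain_tm, ["ghost"])

    def test_arrange_does_not_change_traversal_sets(self, forest_factory):
        tm = forest_factory(6, n_taxa=30, n_obs=40)
        out = man.arrange_taxa(tm, "name", ascending=False)
        out.validate()
        assert set(out.roots()) == set(tm.roots())
        sub_a = out.subtaxa(recursive=True)
        sub_b = tm.subtaxa(recursive=True)
        for t in tm.taxon_ids:
            assert set(sub_a[t]) == set(sub_b[t])

    def test_arrange_is_idempotent(self, forest_factory):
        tm = forest_factory(8, n_taxa=30, n_obs=30)
        tm = man.mutate_taxa(tm, key=np.random.default_rng(0).random(30))
        once = man.arrange_taxa(tm, "key")
        twice = man.arrange_taxa(once, "key")
        pd.testing.assert_frame_equal(once.taxa, twice.taxa)


class TestSampling:
    def test_sample_all_with_uniform_weights_is_identity_selection(self, forest_factory):
        tm = forest_factory(9, n_taxa=20, n_obs=30)
        out = man.sample_n_taxa(tm, 20, seed=1)
        assert out.taxon_ids == tm.taxon_ids

    def test_concentrated_weight_always_selected(self):
        tm = make_taxmap([("A", None), ("B", None), ("C", None)])
        for seed in range(10):
            out = man.sample_n_taxa(tm, 1, weights=[0, 5, 0], seed=seed)
            assert out.taxon_ids == ["B"]

    def test_sample_too_many_errors(self, chain_tm):
        with pytest.raises(TaxmapError, match="cannot sample"):
            man.sample_n_taxa(chain_tm, 4, seed=0)

    def test_all_zero_weights_error(self, chain_tm):
        with pytest.raises(TaxmapError):
            man.sample_n_taxa(chain_tm, 1, weights=[0, 0, 0], seed=0)

    def test_same_seed_reproduces_different_seeds_differ(self, forest_factory):
        tm = forest_factory(10, n_taxa=50, n_obs=80)
        a = man.sample_n_obs(tm, 20, seed=7)
        b = man.sample_n_obs(tm, 20, seed=7)
        c = man.sample_n_obs(tm, 20, seed=8)
        assert a.obs_ids == b.obs_ids
        assert a.obs_ids != c.obs_ids

    def test_weighted_marginals_match_binomial_oracle(self):
        """2 items, weights (2,1), n=1: first picked with p=2/3 (3 SE band)."""
        w = np.array([2.0, 1.0])
        n_rep = 30_000
        rng = np.random.default_rng(123)
        hits = sum(man.weighted_sample_without_replacement(w, 1, rng)[0] == 0
                   for _ in range(n_rep))
        p = 2 / 3
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(hits / n_rep - p) < 3 * se


class TestTaxonomicSample:
    def _ranked(self, seed=0, n_taxa=40, n_obs=200):
        return random_taxmap(FixtureConfig(n_taxa=n_taxa, n_obs=n_obs, seed=seed)).taxmap

    def test_no_limits_is_identity(self):
        tm = self._ranked()
        out = man.taxonomic_sample(tm, "phylum", min_counts=0, max_counts=10**9, seed=0)
        assert sorted(out.obs_ids) == sorted(tm.obs_ids)
        assert out.taxon_ids == tm.taxon_ids

    def test_subsamples_to_exactly_max(self):
        tm = make_taxmap([("A", None), ("B", "A")],
                         [(f"o{i}", "B") for i in range(5)],
                         ranks=["domain", "phylum"])
        out = man.taxonomic_sample(tm, "phylum", max_counts=2, seed=4)
        assert len(out.obs) == 2

    def test_unknown_rank_lists_available(self):
        tm = self._ranked()
        with pytest.raises(TaxmapError, match="available ranks"):
            man.taxonomic_sample(tm, "kingdom")

    @pytest.mark.parametrize("seed", range(8))
    def test_postconditions_on_random_fixtures(self, seed):
        tm = self._ranked(seed=seed, n_taxa=50, n_obs=300)
        rank = "class"
        before = tm.observations([t for t, r in zip(tm.taxon_ids, tm.taxa["rank"])
                                  if r == rank], recursive=True)
        out = man.taxonomic_sample(tm, rank, min_counts=3, max_counts=8, seed=seed)
        out.validate()
        kept = set(out.taxon_ids)
        surviving_obs = set(out.obs_ids)
        for t, obs_ids in before.items():
            if len(obs_ids) < 3:
                assert t not in kept  # all-or-nothing removal below the minimum
                assert not (set(obs_ids) & surviving_obs)
            else:
                assert t in kept
                assert len(set(obs_ids) & surviving_obs) == min(len(obs_ids), 8)

    def test_deterministic_given_seed(self):
        tm = self._ranked(seed=3, n_taxa=50, n_obs=300)
        a = man.taxonomic_sample(tm, "class", min_counts=2, max_counts=6, seed=11)
        b = man.taxonomic_sample(tm, "class", min_counts=2, max_counts=6, seed=11)
        pd.testing.assert_frame_equal(a.obs, b.obs)
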