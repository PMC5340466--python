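"""Hierarchy-aware filtering and sampling.

Filtering a taxonomy is not plain row subsetting: the verbs decide what
happens to subtaxa, supertaxa and observations of removed taxa.  Computed
columns like n_obs re-evaluate automatically, so they are never stale.
"""
from taxomap import FixtureConfig, filter_taxa, random_taxmap, taxonomic_sample

tm = random_taxmap(FixtureConfig(n_taxa=40, n_obs=300, seed=4)).taxmap
print("before:", tm)

# keep only well-sampled taxa; observations of removed taxa climb to their
# nearest surviving ancestor instead of being lost
kept = filter_taxa(tm, "n_obs >= 10", reassign_obs=True)
print("after filter_taxa('n_obs >= 10'):", kept)
print("observations retained:", len(kept.obs), "of", len(tm.obs))

# even out coverage at one rank: drop classes with < 5 observations, cap the
# rest at 20 by uniform subsampling (the classic pre-analysis normalization)
evened = taxonomic_sample(tm, "class", min_counts=5, max_counts=20, seed=1)
counts = evened.taxa_table().query("rank == 'class'")[["name", "n_obs"]]
print("per-class observation counts after taxonomic_sample:")
print(counts.to_string(index=False))
# every surviving class now carries between 5 and 20 observations.
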