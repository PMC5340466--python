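# Methods

This note records the models, conventions and numerical choices behind
taxomap, and what the synthetic test conditions do and do not establish
about real data.

## The Taxmap object

A Taxmap holds two pandas DataFrames. The taxon table is an edge list:
`taxon_id` (opaque, unique, stable — never renumbered by filtering),
`supertaxon_id` (`None` for roots), plus free columns such as `name` and
`rank`. Ranks are free-form strings; databases disagree on rank
vocabularies, so none is enforced. The observation table maps each
`obs_id` to exactly one `taxon_id`; multiple assignment is not supported,
but observations may sit on internal taxa that also have subtaxa (surveys
routinely classify reads to internal nodes when species-level assignment
fails).

Invariants maintained after every public operation: unique IDs,
referential integrity (`observations.taxon_id ⊆ taxa.taxon_id`, every
`supertaxon_id` a valid taxon), and acyclicity — the parent relation is a
forest, checked by reachability from the roots. Every verb returns a new
validated Taxmap; inputs are never mutated.

Derived attributes are *computed columns*: functions `f(taxmap) →
column` kept in a registry and materialized on access (`taxa_table()` /
`obs_table()`), so they always reflect the current tables. If a user
column shares a computed column's name, the user column wins and a
warning is logged. Defaults: `n_obs` (observations in the subtree,
inclusive), `n_obs_direct`, `n_subtaxa`; `digital_pcr` and
`compare_treatments` register more.

Ordering contract: all set-valued traversal results come back in
taxon-table row order (`supertaxa` returns nearest ancestor first).
This makes every example and test reproducible; the order carries no
semantics.

Serialization is two TSVs with `NA` for missing parents; round trips are
lossless for string and integer columns (a numeric-looking string column
would come back numeric — accepted, documented). Newick export emits one
tree per root, names as labels, no branch lengths (these are taxonomic,
not phylogenetic, trees).

## Universal parsing

`ParseSpec` is a regular expression plus a key naming each capture group:
`class` (a lineage string split on `class_separator`, optionally
`rank_separator`-tagged, root-most first unless `reverse_levels`),
`taxon_name`, `taxon_id` (kept verbatim as a `source_taxon_id` column; no
online resolution — the package is fully offline), and `obs_info`
columns. Lineage identity is the full root-path of names: two taxa named
`Incertae_sedis` under different parents stay distinct, which is the only
identity that keeps the forest well defined. When one path arrives with
conflicting rank labels, the first-seen rank wins and the conflict is
logged. Whitespace around level names is stripped; empty levels are
dropped with a warning. Non-matching records either abort with the
offending index (default) or are skipped with a logged count.
`write_lineages` is the inverse; it refuses to render names containing a
separator, because the result could not be re-parsed unambiguously.

## Manipulation verbs

`filter_taxa(pred, keep_subtaxa, keep_supertaxa, reassign_obs,
reassign_taxa, invert)`: the predicate (a `DataFrame.eval` string over
user/computed columns, a callable, or a mask) selects taxa;
`keep_subtaxa`/`keep_supertaxa` expand the selection to descendants /
ancestors; `invert` complements *after* expansion (one fixed rule, since
either order is defensible). Survivors whose parent was removed are
re-parented to the nearest surviving ancestor when `reassign_taxa`
(default), else they become roots — promoting orphans to roots is the
choice that keeps the survivor set exactly as selected without inventing
edges. Observations of removed taxa climb to
the nearest surviving ancestor when `reassign_obs` (default), else they
are dropped. Defaults preserve data unless the user opts out.

`taxonomic_sample(rank, min_counts, max_counts, seed)`: rank-level taxa
below the minimum are removed with their whole subtree (excluded, not
truncated); those above the maximum have their subtree observations
uniformly subsampled to exactly `max_counts`. Taxa of the target rank are
assumed non-nested (true whenever ranks follow depth, as in the
generators); overlapping same-rank taxa would be processed independently.

Weighted sampling without replacement is defined as sequential draws
proportional to the remaining weights — an explicit law with exactly
computable marginals, exposed as `weighted_sample_without_replacement`
so tests can compare frequencies against enumeration. Every stochastic
operation takes an explicit seed; there is no hidden global RNG state.

## Digital PCR

IUPAC codes are 4-bit base sets; two codes match iff the sets intersect.
Binding-site search slides the primer along the template (numpy bitmask
windows) and keeps offsets with at most ⌊p/100 · L⌋ mismatches — percent
of primer length, floored, mirroring common primer-search semantics. A
template amplifies iff some forward site has a reverse-complemented
reverse-primer site starting at or after the forward site's end; the
product runs from forward start to reverse-site end. Among qualifying
pairs the shortest product wins, ties broken by leftmost forward site —
arbitrary but fixed and documented. Only the given strand is scanned by
default (reference databases are orientation-normalized);
`both_strands=True` also scans the reverse complement and reports the
scanned strand. Optional min/max product-length bounds; no
thermodynamics, dimers or gapped alignment. Per-taxon `prop_amplified` =
amplified subtree observations / `n_obs`; taxa with an empty subtree get
0.0 rather than NaN so aesthetic mapping never sees missing values.

## Two-group comparison

Per sample, counts are normalized to proportions over exactly the taxa in
the supplied matrix (no subtree re-normalization — "proportion of reads"
semantics). Per taxon: log₂(median_A/median_B); the Wilcoxon rank-sum
test (scipy's Mann–Whitney U: exact enumeration for pooled n ≤ 12
without ties, otherwise normal approximation with tie and continuity
corrections — at 8 vs 8 the two differ by at most ~0.011 in our checks);
BH adjustment across all tested taxa (statsmodels step-up); significance
gate at alpha (default 0.05, conventional). Zero-median policy: both
medians 0 → ratio 0; exactly one 0 → ±(max finite |ratio| + 1), flagged
`ratio_capped`, so presence/absence outranks every finite fold change
without infinities and remains antisymmetric under group swap. No
prevalence filter by default (`min_prevalence` exists); no CLR or other
compositional transform — strong effects therefore induce small
compositional shifts in other taxa's proportions, which is visible in
null-vs-planted simulations and is a property of proportion data itself.

## Heat trees

Layout: the layered mode assigns leaves consecutive x slots in row order
and centers each internal node over its children (y = −depth); subtrees
occupy disjoint leaf intervals, so extents never overlap, and the result
is fully deterministic. The force-directed mode refines that start with
networkx's spring layout under a fixed seed. One sub-tree per root,
arranged on a near-square grid, each uniformly scaled into its cell with
a 12 % margin.

Size range: the upper node radius is chosen by 20-iteration bisection
over the candidate interval (defaults 0.006–0.045 of the figure) such
that, with all nodes at that radius, total pairwise disc-intersection
area ≤ 1 % of total disc area (falling back to the smallest candidate);
the lower bound is a fixed quarter of the upper. The 1 % tolerance and
the bisection make "minimize overlap, maximize size" an explicit,
testable objective. The check is conservative (it assumes every node at
the maximal radius).

Aesthetics: values pass through identity/log10/sqrt, then an affine map
onto the size interval (constant columns map to the midpoint) or
piecewise-linear RGB interpolation through the palette anchors, spaced
evenly over the value interval — an odd anchor count therefore puts the
middle anchor at the interval midpoint, as a diverging palette wants.
Explicit `size_interval`/`color_interval` override the data range and
clamp. RGB-space interpolation keeps the oracle trivial; perceptual
spaces would be an extension, not the default. Edge polygons taper
linearly between the half-radii of their end nodes. Labels scale with
their node, floor at 0.007 figure units, and truncate with an ellipsis.

Rendering computes a backend-neutral display list in normalized
[0,1]² coordinates; SVG is serialized directly from it with fixed float
formatting (hence byte-identical for identical inputs and seed, and
trivially parseable back for coordinate checks), while PNG/PDF are drawn
from the same display list via matplotlib. Legend metadata — tick values
in raw units plus their mapped sizes/colors — is emitted as
`<output>.legend.json`; visual legend panels are drawn for the node
mappings, and edge-mapping metadata is included in the JSON.

## Synthetic study conditions

`random_taxmap` attaches each new taxon uniformly to an existing taxon
with spare capacity (capacity ≈ Poisson around the branching mean) above
the depth limit; ranks follow depth; observations land uniformly.
`random_sequences` plants a realized forward site and a downstream
reverse-complement reverse site at recorded positions, with a recorded
number of injected mismatches (each injected base is chosen to *not*
match the degenerate probe position). `random_abundance` draws
log-normal baseline weights (σ = 1.5 — a long-tailed, microbiome-like
rank-abundance shape), multiplies group-B weights by the planted fold
changes, and draws multinomial counts at a fixed library size of 10,000
reads per sample; default design is 10 samples per group with 30 taxa in
the statistical simulations, and a 4-fold planted effect for recovery
checks.

What passing these conditions does *not* show: robustness to real
database taxonomies (ragged depths, huge fan-outs), sequencing error or
chimeras in the PCR templates, overdispersed (non-multinomial) count
noise, or batch structure between sample groups. The statistics are the
standard nonparametric stack and inherit its properties; the generators
exist to make the *machinery* exactly checkable against ground truth,
not to simulate any particular ecosystem.

## Problem sizes

The test suite runs 1,000-forest traversal sweeps (≤ 200 taxa, ≤ 500
observations), 200 filter cases × 16 flag combinations × both re-parent
modes, 200 parser round trips, 500 PCR fixtures across three mismatch
budgets, 500 null and 200 planted-effect simulations (30 taxa, 10 vs 10
samples), and 30,000 sampling replicates — all seeded, completing in
about a minute on one CPU. `scripts/acceptance.py` re-runs the same
pipeline at comparable sizes from a single command-line seed.
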