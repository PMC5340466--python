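"""Pairwise community comparison between two sample groups.

For every taxon in an abundance matrix: the log2 ratio of median per-sample
read proportions between the groups, a two-sided Wilcoxon rank-sum p-value,
Benjamini-Hochberg FDR adjustment across taxa, and a significance-gated
version of the ratio (zero where not significant) ready to drive heat-tree
node color, so that only statistically supported differences are colored.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Taxmap, TaxmapError

#: group sizes up to this total use the exact rank-sum null (no ties)
EXACT_MAX_N = 12


def read_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample (column) to proportions summing to 1."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise TaxmapError(f"sample {zero.index[0]!r} has zero total count")
    return counts / sums


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null by enumeration when the pooled size is at most
    :data:`EXACT_MAX_N` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise TaxmapError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                    use_continuity=True).pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise TaxmapError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Per-taxon comparison table plus the Taxmap annotated for plotting.

    ``table`` columns: log2_ratio, ratio_capped, p_raw, p_adjusted,
    significant; indexed by taxon_id.  ``taxmap`` carries computed columns
    ``log2_ratio``, ``log2_ratio_gated`` and ``p_adjusted`` (taxa absent
    from the matrix get 0 / 0 / 1).
    """

    table: pd.DataFrame
    taxmap: Taxmap | None
    group_a: str
    group_b: str
    alpha: float


def _log2_ratios(med_a: np.ndarray, med_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log2(median_a / median_b) with an explicit zero-median policy.

    Both medians zero -> ratio 0.  Exactly one zero -> the ratio is capped at
    +/-(max finite |ratio| among taxa + 1) and flagged, so one-sided presence
    still ranks above every finite fold change without producing infinities.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log2(med_a / med_b)
    finite = np.isfinite(raw)
    cap = (np.max(np.abs(raw[finite])) if finite.any() else 0.0) + 1.0
    ratio = np.where(finite, raw, 0.0)
    capped = np.zeros(len(raw), dtype=bool)
    one_zero = (med_a > 0) != (med_b > 0)
    ratio = np.where(one_zero & (med_a > 0), cap, ratio)
    ratio = np.where(one_zero & (med_b > 0), -cap, ratio)
    capped |= one_zero
    return ratio, capped


def compare_treatments(tm: Taxmap | None, counts: pd.DataFrame, groups,
                       group_a: str, group_b: str, alpha: float = 0.05,
                       min_prevalence: int = 0) -> ComparisonResult:
    """Compare per-taxon read proportions between two treatment groups.

    Parameters
    ----------
    tm:
        Optional Taxmap used to annotate taxa for plotting; every row index
        of ``counts`` must be one of its taxon_ids when given.
    counts:
        Abundance matrix, rows = taxon_id, columns = samples, non-negative
        counts.
    groups:
        Mapping/Series sample -> treatment label.
    min_prevalence:
        Taxa present (count > 0) in fewer samples are excluded from testing.
    """
    groups = pd.Series(groups)
    for g in (group_a, group_b):
        if g not in set(groups.values):
            raise TaxmapError(f"unknown treatment label {g!r}")
    samples_a = [s for s in counts.columns if groups.get(s) == group_a]
    samples_b = [s for s in counts.columns if groups.get(s) == group_b]
    if tm is not None:
        known = set(tm.taxon_ids)
        missing = [t for t in counts.index if t not in known]
        if missing:
            raise TaxmapError(f"matrix row {missing[0]!r} is not a taxon of the Taxmap")

    used = list(dict.fromkeys(samples_a + samples_b))  # unique, order kept
    props = read_proportions(counts[used])
    tested = counts.index
    if min_prevalence > 0:
        prevalence = (counts[used] > 0).sum(axis=1)
        tested = counts.index[prevalence >= min_prevalence]
    pa = props.loc[tested, samples_a]
    pb = props.loc[tested, samples_b]
    med_a = pa.median(axis=1).to_numpy()
    med_b = pb.median(axis=1).to_numpy()
    ratio, capped = _log2_ratios(med_a, med_b)
    p_raw = np.array([wilcoxon_rank_sum(pa.loc[t], pb.loc[t]) for t in tested])
    p_adj = benjamini_hochberg(p_raw)
    significant = p_adj < alpha
    table = pd.DataFrame({
        "log2_ratio": ratio,
        "ratio_capped": capped,
        "p_raw": p_raw,
        "p_adjusted": p_adj,
        "significant": significant,
    }, index=pd.Index(tested, name="taxon_id"))

    annotated = None
    if tm is not None:
        annotated = tm.copy()
        gated = table["log2_ratio"].where(table["significant"], 0.0)

        def col(series, default):
            mapping = series.to_dict()
            return lambda t: np.array([mapping.get(tid, default) for tid in t.taxon_ids])

        annotated.register_taxon_func("log2_ratio", col(table["log2_ratio"], 0.0))
        annotated.register_taxon_func("log2_ratio_gated", col(gated, 0.0))
        annotated.register_taxon_func("p_adjusted", col(table["p_adjusted"], 1.0))
    return ComparisonResult(table=table, taxmap=annotated,
                            group_a=group_a, group_b=group_b, alpha=alpha)
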