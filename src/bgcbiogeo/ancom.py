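"""ANCOM-style compositional differential abundance between two sites.

Species relative abundances are first converted to estimated read
counts (RA x post-QC total reads), filtered (low-depth samples, rare or
shallow taxa), and zero-replaced with a pseudocount of one.  For every
taxon i, the log-ratio of taxon i to each other taxon j is tested
between the two groups with a two-sided Wilcoxon rank-sum test;
Benjamini-Hochberg correction is applied within taxon i's m-1 tests,
and W_i counts the rejections.  A taxon is called differential when its
W statistic reaches the empirical 90th percentile of all W values and
the between-group difference of its mean centered-log-ratio (CLR) value
exceeds 0.5 in absolute value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import TaxaTable

__all__ = ["estimated_taxon_counts", "ancom_filter", "ancom_w"]


def estimated_taxon_counts(taxa: TaxaTable) -> pd.DataFrame:
    """Estimated per-taxon read counts: round(RA x total post-QC reads)."""
    if taxa.total_reads is None or taxa.total_reads.isna().any():
        raise ValueError("per-sample total_reads required to estimate counts")
    counts = taxa.abundances.mul(taxa.total_reads, axis=0)
    return counts.round().astype(np.int64)


def ancom_filter(
    counts: pd.DataFrame,
    min_sample_total: int = 10_000,
    min_prevalence: int = 10,
    min_taxon_total: int = 1_000,
) -> pd.DataFrame:
    """Drop shallow samples, then rare or low-count taxa.

    Samples with fewer than ``min_sample_total`` total estimated reads
    are excluded; taxa present in fewer than ``min_prevalence`` samples
    or with a grand total below ``min_taxon_total`` reads are excluded.
    """
    deep = counts.sum(axis=1) >= min_sample_total
    out = counts.loc[deep]
    if out.empty:
        raise ValueError("every sample fell below the depth cutoff")
    prevalence = (out > 0).sum(axis=0)
    grand = out.sum(axis=0)
    keep = (prevalence >= min_prevalence) & (grand >= min_taxon_total)
    out = out.loc[:, keep]
    if out.shape[1] == 0:
        raise ValueError("every taxon was filtered out")
    return out


def ancom_w(
    counts: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    clr_threshold: float = 0.5,
    w_percentile: float = 90.0,
) -> pd.DataFrame:
    """W statistics and CLR differences between exactly two groups.

    Returns a DataFrame indexed by taxon with columns ``W``,
    ``mean_clr_difference``, ``differential``.
    """
    groups = groups.loc[counts.index]
    names = groups.unique()
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {list(names)}")
    mask_a = (groups == names[0]).to_numpy()
    mask_b = ~mask_a
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least two samples")
    m = counts.shape[1]
    if m < 2:
        raise ValueError("need at least two taxa")
    # pseudocount 1 on zeros only: log(c) for c>0, log(1)=0 for c==0
    zero_replaced = counts.to_numpy(dtype=float)
    zero_replaced[zero_replaced == 0] = 1.0
    log_counts = np.log(zero_replaced)
    # pairwise log-ratio tests (p_ij symmetric: computed once per pair)
    p_matrix = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ratio = log_counts[:, i] - log_counts[:, j]
            res = stats.mannwhitneyu(
                ratio[mask_a], ratio[mask_b], alternative="two-sided"
            )
            p_matrix[i, j] = p_matrix[j, i] = res.pvalue
    w = np.zeros(m, dtype=int)
    for i in range(m):
        others = np.delete(p_matrix[i], i)
        rejected = multipletests(others, method="fdr_bh")[1] < alpha
        w[i] = int(rejected.sum())
    clr = log_counts - log_counts.mean(axis=1, keepdims=True)
    mean_clr_diff = clr[mask_a].mean(axis=0) - clr[mask_b].mean(axis=0)
    w_cut = np.percentile(w, w_percentile)
    differential = (np.abs(mean_clr_diff) > clr_threshold) & (w >= w_cut)
    return pd.DataFrame(
        {
            "W": w,
            "mean_clr_difference": mean_clr_diff,
            "differential": differential,
        },
        index=counts.columns.rename("species"),
    )
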