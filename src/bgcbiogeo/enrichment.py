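"""One-vs-rest differential BGC abundance with a negative-binomial
Wald test.

For a focal body site, each BGC's size-factor-normalized counts in the
focal samples are compared against all remaining samples.  The effect
is the log2 fold change of group means; its standard error comes from
the delta method under a negative-binomial variance (mu + alpha mu^2)
with a method-of-moments dispersion pooled within groups.  P values are
two-sided Wald, Benjamini-Hochberg adjusted within each focal-site
contrast, and a BGC is called enriched when the fold change is at least
``min_fold`` (inclusive, enrichment direction only) with adjusted
p below ``max_padj``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountMatrix

__all__ = ["select_enrichment_sites", "nb_wald_one_vs_rest"]

#: Floor on the method-of-moments dispersion estimate.
ALPHA_MIN = 1e-8
_LN2_SQ = np.log(2.0) ** 2


def select_enrichment_sites(
    metadata: pd.DataFrame, min_samples: int = 200
) -> list[str]:
    """Sites with at least ``min_samples`` samples, in size order."""
    counts = metadata["site"].value_counts()
    return [str(s) for s, n in counts.items() if n >= min_samples]


def _pooled_dispersion(
    focal: np.ndarray, rest: np.ndarray
) -> np.ndarray:
    """Method-of-moments NB dispersion pooled within the two groups.

    alpha = max(ALPHA_MIN, (s2 - mu) / mu^2) per BGC, using the pooled
    within-group variance and the grand mean of normalized counts.
    """
    n_f, n_r = focal.shape[1], rest.shape[1]
    var_f = focal.var(axis=1, ddof=1)
    var_r = rest.var(axis=1, ddof=1)
    pooled_var = ((n_f - 1) * var_f + (n_r - 1) * var_r) / (n_f + n_r - 2)
    grand_mean = (focal.sum(axis=1) + rest.sum(axis=1)) / (n_f + n_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - grand_mean) / grand_mean**2
    return np.maximum(ALPHA_MIN, np.nan_to_num(alpha, nan=ALPHA_MIN))


def nb_wald_one_vs_rest(
    m: CountMatrix,
    metadata: pd.DataFrame,
    focal_site: str,
    min_fold: float = 4.0,
    max_padj: float = 1e-8,
) -> pd.DataFrame:
    """Enrichment of each BGC in ``focal_site`` against all other sites.

    Returns a DataFrame indexed by BGC id with columns ``site``, ``lfc``,
    ``se``, ``p``, ``padj``, ``enriched``.
    """
    if m.state not in {"pseudocounted", "normalized"}:
        raise ValueError("count matrix must be pseudocounted (or normalized)")
    values = m.values_for_analysis()
    sites = metadata.loc[values.columns, "site"]
    focal_mask = (sites == focal_site).to_numpy()
    if not focal_mask.any():
        raise ValueError(f"no samples from focal site {focal_site!r}")
    if focal_mask.all():
        raise ValueError("rest group is empty")
    data = values.to_numpy(dtype=float)
    focal = data[:, focal_mask]
    rest = data[:, ~focal_mask]
    mu_f = focal.mean(axis=1)
    mu_r = rest.mean(axis=1)
    lfc = np.log2(mu_f / mu_r)
    alpha = _pooled_dispersion(focal, rest)
    # delta method: var(log2 mu_hat) = (mu + alpha mu^2) / (n mu^2 ln^2 2)
    var_f = (mu_f + alpha * mu_f**2) / (focal.shape[1] * mu_f**2 * _LN2_SQ)
    var_r = (mu_r + alpha * mu_r**2) / (rest.shape[1] * mu_r**2 * _LN2_SQ)
    se = np.sqrt(var_f + var_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]
    enriched = (lfc >= np.log2(min_fold)) & (padj < max_padj)
    return pd.DataFrame(
        {
            "site": focal_site,
            "lfc": lfc,
            "se": se,
            "p": p,
            "padj": padj,
            "enriched": enriched,
        },
        index=values.index.rename("bgc_id"),
    )
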