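"""Alpha-diversity metrics and the supporting univariate statistics.

Shannon diversity H' (natural log), richness S, and Shannon equitability
E_H = H'/ln(S) are computed on species relative-abundance profiles and
on per-sample BGC read proportions.  Differences in H' across body
sites are tested with Kruskal-Wallis plus post hoc Dunn tests
(Benjamini-Hochberg corrected) summarized as a compact letter display,
with epsilon-squared as the effect size.  A sign test compares paired
diversity values, Kendall's tau-b measures rank correlation, and an
ordinary least-squares fit relates BGC-level to species-level H' within
each site.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiversityResult",
    "GroupTestResult",
    "shannon_metrics",
    "kruskal_dunn",
    "sign_test",
    "kendall_tau_b",
    "diversity_regression",
]

logger = logging.getLogger(__name__)


@dataclass
class DiversityResult:
    shannon: float
    richness: int
    equitability: Optional[float]


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    epsilon_squared: float
    dunn: pd.DataFrame  # columns: group_a, group_b, z, p, p_adjusted
    letters: dict[str, str]


def shannon_metrics(profile: Sequence[float]) -> DiversityResult:
    """Shannon H' (nats), richness S, and equitability E_H = H'/ln S.

    The input is any nonnegative abundance vector; proportions are taken
    internally, so H' is invariant to rescaling.  E_H is undefined
    (``None``) when S <= 1.
    """
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("profile entries must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("profile sums to zero")
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    richness = int((x > 0).sum())
    equitability = shannon / np.log(richness) if richness >= 2 else None
    return DiversityResult(shannon=shannon, richness=richness, equitability=equitability)


def _tie_term(ranks: np.ndarray) -> float:
    """Dunn tie correction sum: sum(t^3 - t) over tied groups."""
    _, counts = np.unique(ranks, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def _compact_letters(
    groups: list[str],
    medians: Mapping[str, float],
    significant: set[frozenset],
) -> dict[str, str]:
    """Greedy compact letter display.

    Groups are processed in descending order of median; each is added to
    every existing letter column whose members it does not differ from
    significantly, opening a new column when none accepts it.
    """
    order = sorted(groups, key=lambda g: -medians[g])
    columns: list[set[str]] = []
    for g in order:
        placed = False
        for col in columns:
            if all(frozenset((g, other)) not in significant for other in col):
                col.add(g)
                placed = True
        if not placed:
            columns.append({g})
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupTestResult:
    """Kruskal-Wallis across groups with post hoc Dunn tests.

    Dunn z statistics use midranks with tie correction; p values are
    two-sided and BH-adjusted jointly across all pairs.  The effect size
    is epsilon-squared, H/(n-1).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
    h_stat, p_value = stats.kruskal(*arrays.values())
    pooled = np.concatenate([arrays[g] for g in names])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [arrays[g].size for g in names])
    mean_rank = {
        g: float(ranks[offsets[i] : offsets[i + 1]].mean())
        for i, g in enumerate(names)
    }
    tie = _tie_term(ranks)
    base_var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = arrays[a].size, arrays[b].size
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    dunn = pd.DataFrame(rows)
    if len(dunn):
        dunn["p_adjusted"] = multipletests(dunn["p"], method="fdr_bh")[1]
    else:
        dunn["p_adjusted"] = []
    significant = {
        frozenset((r.group_a, r.group_b))
        for r in dunn.itertuples()
        if r.p_adjusted < alpha
    }
    medians = {g: float(np.median(arrays[g])) for g in names}
    letters = _compact_letters(names, medians, significant)
    epsilon_sq = float(h_stat) / (n - 1)
    return GroupTestResult(
        statistic=float(h_stat),
        p_value=float(p_value),
        epsilon_squared=epsilon_sq,
        dunn=dunn,
        letters=letters,
    )


def sign_test(a: Sequence[float], b: Sequence[float]) -> tuple[int, float]:
    """Paired sign test: S = #{a_i > b_i} after dropping ties.

    The two-sided p value is exact binomial up to n = 1000 and a
    continuity-corrected normal approximation beyond that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    nonzero = diff != 0
    n = int(nonzero.sum())
    if n == 0:
        raise ValueError("all pairs are tied")
    s = int((diff > 0).sum())
    if n <= 1000:
        p = stats.binomtest(s, n, 0.5, alternative="two-sided").pvalue
    else:
        z = (abs(s - n / 2.0) - 0.5) / np.sqrt(n / 4.0)
        p = 2.0 * stats.norm.sf(z)
    return s, float(min(1.0, p))


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation tau-b with normal-
    approximation p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau_b undefined for a constant vector")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def diversity_regression(
    h_species: Sequence[float],
    h_bgc: Sequence[float],
    sites: Sequence[str],
) -> pd.DataFrame:
    """Per-site (and overall) OLS of BGC-level H' on species-level H'.

    Pairs with species H' of 0 are removed before fitting.  Sites left
    with fewer than 3 pairs are skipped with a warning.  Returns one row
    per site plus an ``overall`` row with R-squared, slope-test p, and n.
    """
    hs = np.asarray(h_species, dtype=float)
    hb = np.asarray(h_bgc, dtype=float)
    sites = np.asarray(sites)
    keep = hs > 0
    hs, hb, sites = hs[keep], hb[keep], sites[keep]
    rows = []

    def _fit(label: str, xs: np.ndarray, ys: np.ndarray) -> None:
        if xs.size < 3:
            logger.warning("site %s: fewer than 3 pairs after filtering; skipped", label)
            return
        fit = stats.linregress(xs, ys)
        rows.append(
            {
                "site": label,
                "r_squared": float(fit.rvalue**2),
                "slope": float(fit.slope),
                "p_value": float(fit.pvalue),
                "n": int(xs.size),
            }
        )

    for site in pd.unique(sites):
        mask = sites == site
        _fit(str(site), hs[mask], hb[mask])
    _fit("overall", hs, hb)
    return pd.DataFrame(rows).set_index("site")
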