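"""Beta-diversity and community structure across body sites.

Bray-Curtis dissimilarities between sample profiles feed three
complementary views of site structure: ANOSIM (a rank-based permutation
test of between- versus within-site dissimilarity), nonmetric
multidimensional scaling (NMDS, minimizing Kruskal stress-1 against a
monotone regression of configuration distances on dissimilarity ranks),
and Ward minimum-variance hierarchical clustering with per-cluster site
purity.  A pair-counting Jaccard index measures agreement between two
clusterings of the same samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

from .tables import TaxaTable

__all__ = [
    "DistanceMatrix",
    "AnosimResult",
    "NmdsResult",
    "ClusteringResult",
    "species_filter",
    "bray_curtis",
    "anosim",
    "nmds",
    "ward_cluster",
    "clustering_jaccard",
    "linkage_to_newick",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="sample_id"
        )


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: pd.Series
    purity: dict[int, float]
    majority_site: dict[int, str]


def species_filter(
    taxa: TaxaTable, min_ra: float = 0.001, min_prevalence: int = 25
) -> TaxaTable:
    """Apply the standard pre-ordination species filters.

    Entries below ``min_ra`` relative abundance are zeroed; any species
    reaching 100% relative abundance in some sample is removed (such
    samples are effectively monocultures and the species dominates the
    ordination); species detected in fewer than ``min_prevalence``
    samples after zeroing are removed.
    """
    ab = taxa.abundances.copy()
    at_full = (ab >= 1.0 - 1e-12).any(axis=0)
    ab = ab.loc[:, ~at_full]
    values = ab.to_numpy(dtype=float)
    values[values < min_ra] = 0.0
    prevalence = (values > 0).sum(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise ValueError("species filter removed every species")
    filtered = pd.DataFrame(
        values[:, keep], index=ab.index, columns=ab.columns[keep]
    )
    return TaxaTable(abundances=filtered, total_reads=taxa.total_reads)


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, sum|u-v| / sum(u+v), between rows."""
    values = profiles.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("profiles must be nonnegative")
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        bad = [profiles.index[i] for i in zero_rows[:5]]
        raise ValueError(f"Bray-Curtis undefined between all-zero rows: {bad}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(
        ids=list(profiles.index), matrix=squareform(condensed), metric="braycurtis"
    )


def _anosim_r_from_within(
    within_sum: float, n_within: int, n_between: int, denom: float, total: float
) -> float:
    rw = within_sum / n_within
    rb = (total - within_sum) / n_between
    return (rb - rw) / denom


def anosim(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    All pairwise distances are midranked; R contrasts the mean rank of
    between-group pairs with that of within-group pairs, scaled by
    n(n-1)/4.  The p value comes from random relabelings (with the +1
    correction counting the observed statistic), or from exhaustive
    enumeration of all distinct relabelings when ``n_perm="exact"``.
    """
    labels = np.asarray(groups)
    n = d.n
    if len(labels) != n:
        raise ValueError("one group label per sample required")
    names, inverse = np.unique(labels, return_inverse=True)
    if len(names) < 2:
        raise ValueError("ANOSIM requires at least two groups")
    sizes = np.bincount(inverse)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    ranks_condensed = stats.rankdata(d.condensed())
    rank_matrix = squareform(ranks_condensed)
    total = float(ranks_condensed.sum())
    n_pairs = n * (n - 1) // 2
    n_within = int((sizes * (sizes - 1) // 2).sum())
    n_between = n_pairs - n_within
    if n_between == 0:
        raise ValueError("ANOSIM needs at least one between-group pair")
    denom = n * (n - 1) / 4.0

    def _within_sum(assign: np.ndarray) -> float:
        onehot = np.zeros((n, len(names)))
        onehot[np.arange(n), assign] = 1.0
        return 0.5 * float(np.sum((rank_matrix @ onehot) * onehot))

    r_obs = _anosim_r_from_within(
        _within_sum(inverse), n_within, n_between, denom, total
    )
    if n_perm == "exact":
        count_ge = 0
        count_total = 0
        for perm in set(itertools.permutations(inverse)):
            count_total += 1
            r_perm = _anosim_r_from_within(
                _within_sum(np.asarray(perm)), n_within, n_between, denom, total
            )
            if r_perm >= r_obs - 1e-12:
                count_ge += 1
        return AnosimResult(
            r=r_obs, p_value=count_ge / count_total, n_permutations=count_total
        )
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(inverse)
        r_perm = _anosim_r_from_within(
            _within_sum(perm), n_within, n_between, denom, total
        )
        if r_perm >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + int(n_perm))
    return AnosimResult(r=r_obs, p_value=p, n_permutations=int(n_perm))


def _classical_scaling(matrix: np.ndarray, k: int) -> np.ndarray:
    n = matrix.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (matrix**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    coords = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    return coords


def _stress_and_dhat(
    d_config: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    dhat = np.empty_like(d_config)
    dhat[order] = isotonic_regression(d_config[order])
    denom = float((d_config**2).sum())
    if denom == 0:
        return np.inf, dhat
    stress = np.sqrt(((d_config - dhat) ** 2).sum() / denom)
    return float(stress), dhat


def _nmds_single(
    dissim: np.ndarray,
    order: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool]:
    n = x0.shape[0]
    x = x0 - x0.mean(axis=0)
    prev_stress = np.inf
    converged = False
    for _ in range(max_iter):
        d_config = pdist(x)
        stress, dhat = _stress_and_dhat(d_config, order)
        if prev_stress - stress < tol * max(prev_stress, 1e-12):
            converged = True
            break
        prev_stress = stress
        # Guttman transform toward the monotone targets
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_config > 0, dhat / d_config, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        x -= x.mean(axis=0)
    d_config = pdist(x)
    stress, _ = _stress_and_dhat(d_config, order)
    return x, stress, converged


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    trymax: int = 100,
    seed: Optional[int] = None,
    max_iter: int = 300,
    tol: float = 1e-7,
    no_improvement_stop: int = 10,
) -> NmdsResult:
    """Nonmetric multidimensional scaling by majorization.

    The first start is classical (metric) scaling; up to ``trymax - 1``
    further random starts follow, stopping early after
    ``no_improvement_stop`` consecutive starts without improvement.  The
    best configuration is returned centered and rotated onto its
    principal axes.
    """
    if d.n < 4:
        raise ValueError("NMDS requires at least 4 samples")
    dissim = d.condensed()
    if not np.isfinite(dissim).all():
        raise ValueError("distances must be finite")
    order = np.argsort(dissim, kind="stable")
    rng = np.random.default_rng(seed)
    best: Optional[tuple[np.ndarray, float, bool]] = None
    since_improvement = 0
    n_restarts = 0
    for attempt in range(max(1, trymax)):
        if attempt == 0:
            x0 = _classical_scaling(d.matrix, k)
        else:
            x0 = rng.normal(size=(d.n, k))
        x, stress, converged = _nmds_single(dissim, order, x0, max_iter, tol)
        n_restarts += 1
        if best is None or stress < best[1] - 1e-12:
            best = (x, stress, converged)
            since_improvement = 0
        else:
            since_improvement += 1
        if best[1] < 1e-6 or since_improvement >= no_improvement_stop:
            break
    assert best is not None
    x, stress, converged = best
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    coords = x @ vt.T
    return NmdsResult(
        coordinates=coords, stress=stress, n_restarts=n_restarts, converged=converged
    )


def ward_cluster(
    values: pd.DataFrame,
    sites: Sequence[str],
    n_clusters: Optional[int] = None,
    transform=np.log10,
) -> ClusteringResult:
    """Ward minimum-variance clustering of samples with site purity.

    ``values`` has samples as rows (e.g. size-factor-normalized BGC
    counts, log10-transformed by default before clustering).  The tree
    is cut at K = number of distinct sites unless ``n_clusters`` is
    given; purity of a cluster is the fraction of its samples from its
    majority site.
    """
    if len(values) < 2:
        raise ValueError("need at least two samples")
    sites = pd.Series(np.asarray(sites), index=values.index, name="site")
    data = values.to_numpy(dtype=float)
    if transform is not None:
        data = transform(data)
    if not np.isfinite(data).all():
        raise ValueError("non-finite values after transform (zeros under log?)")
    k = n_clusters if n_clusters is not None else sites.nunique()
    if k > len(values):
        raise ValueError("more clusters requested than samples")
    z = linkage(data, method="ward")
    flat = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=values.index, name="cluster")
    purity: dict[int, float] = {}
    majority: dict[int, str] = {}
    for cluster_id, members in labels.groupby(labels):
        site_counts = sites.loc[members.index].value_counts()
        majority[int(cluster_id)] = str(site_counts.index[0])
        purity[int(cluster_id)] = float(site_counts.iloc[0] / len(members))
    return ClusteringResult(linkage=z, labels=labels, purity=purity, majority_site=majority)


def clustering_jaccard(labels_a: Sequence, labels_b: Sequence) -> float:
    """Pair-counting Jaccard agreement between two partitions.

    Over all unordered sample pairs, J = n11 / (n11 + n10 + n01) where
    n11 counts pairs co-clustered in both partitions and n10/n01 pairs
    co-clustered in exactly one.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("partitions must label the same samples")
    if a.size < 2:
        raise ValueError("need at least two samples")
    contingency = pd.crosstab(a, b).to_numpy()

    def _pairs(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    n11 = _pairs(contingency)
    pairs_a = _pairs(contingency.sum(axis=1))
    pairs_b = _pairs(contingency.sum(axis=0))
    denom = pairs_a + pairs_b - n11
    return n11 / denom if denom > 0 else 0.0


def linkage_to_newick(z: np.ndarray, ids: Sequence[str]) -> str:
    """Export a SciPy linkage matrix as a Newick string."""
    tree = to_tree(z)

    def _walk(node) -> str:
        if node.is_leaf():
            return f"{ids[node.id]}:{node.dist:.6g}"
        left = _walk(node.get_left())
        right = _walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return f"({_walk(tree.get_left())},{_walk(tree.get_right())});"
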