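"""Bray-Curtis, ANOSIM, NMDS, Ward clustering, and partition agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bgcbiogeo.community import (
    DistanceMatrix,
    anosim,
    bray_curtis,
    clustering_jaccard,
    linkage_to_newick,
    nmds,
    species_filter,
    ward_cluster,
)
from bgcbiogeo.tables import TaxaTable


# ---------------------------------------------------------- species filter

def _taxa(df):
    return TaxaTable(abundances=df, total_reads=pd.Series(10_000, index=df.index))


def test_species_filter_zeroes_and_drops():
    df = pd.DataFrame(
        {
            "rare": [0.0009] * 30,          # below RA threshold everywhere
            "mono": [0.0] * 30,             # hits 100% RA in one sample
            "sparse": [0.2] * 10 + [0.0] * 20,  # present in 10 < 25 samples
            "good": [0.3] * 30,
        },
        index=[f"s{i}" for i in range(30)],
    )
    df.iloc[0] = 0.0
    df.iloc[0, df.columns.get_loc("mono")] = 1.0
    filtered = species_filter(_taxa(df), min_ra=0.001, min_prevalence=25)
    assert list(filtered.abundances.columns) == ["good"]


def test_species_filter_survivors_match_hand_count():
    df = pd.DataFrame(
        {
            "a": [0.2, 0.2, 0.0005],
            "b": [0.0005, 0.0004, 0.0003],
            "c": [0.3, 0.3, 0.3],
        },
        index=["s1", "s2", "s3"],
    )
    filtered = species_filter(_taxa(df), min_ra=0.001, min_prevalence=2)
    assert set(filtered.abundances.columns) == {"a", "c"}
    assert filtered.abundances.loc["s3", "a"] == 0.0


def test_species_filter_can_empty_out():
    df = pd.DataFrame({"a": [0.0005, 0.0005]}, index=["s1", "s2"])
    with pytest.raises(ValueError):
        species_filter(_taxa(df), min_ra=0.001, min_prevalence=1)


# ------------------------------------------------------------- bray-curtis

def test_bray_curtis_examples():
    df = pd.DataFrame(
        [[1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 1.0, 0.0], [2.0, 0.0, 0.0]],
        index=["u", "v", "u2", "w"],
    )
    dm = bray_curtis(df)
    i = {name: k for k, name in enumerate(dm.ids)}
    assert dm.matrix[i["u"], i["v"]] == pytest.approx(0.5)
    assert dm.matrix[i["u"], i["u2"]] == pytest.approx(0.0)
    assert dm.matrix[i["v"], i["w"]] == pytest.approx(1.0)  # disjoint supports


def test_bray_curtis_rejects_two_zero_rows():
    df = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
    with pytest.raises(ValueError):
        bray_curtis(df)


# ------------------------------------------------------------------ anosim

def _separated_dm():
    # two tight groups far apart: all within < all between
    coords = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        ids=[f"s{i}" for i in range(6)],
        matrix=squareform(pdist(coords)),
        metric="euclidean",
    )


def test_anosim_maximal_separation_r_is_one():
    res = anosim(_separated_dm(), ["a", "a", "a", "b", "b", "b"], n_perm="exact")
    assert res.r == pytest.approx(1.0)
    # only the true split and its mirror reach R = 1 among the C(6,3)
    # distinct relabelings
    assert res.p_value == pytest.approx(2 / 20)


def test_anosim_matches_exhaustive_relabeling_oracle():
    """R and exact p agree with brute-force enumeration of all
    distinct relabelings of a 6-sample two-group design."""
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(6, 3))
    from scipy.spatial.distance import pdist, squareform
    from scipy.stats import rankdata

    matrix = squareform(pdist(coords))
    dm = DistanceMatrix(ids=[f"s{i}" for i in range(6)], matrix=matrix, metric="e")
    labels = ["a", "a", "a", "b", "b", "b"]

    def oracle_r(lab):
        ranks = squareform(rankdata(pdist(coords)))
        within, between = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                (within if lab[i] == lab[j] else between).append(ranks[i, j])
        return (np.mean(between) - np.mean(within)) / (6 * 5 / 4)

    res = anosim(dm, labels, n_perm="exact")
    assert res.r == pytest.approx(oracle_r(labels), abs=1e-12)
    perms = set(itertools.permutations(labels))
    r_all = [oracle_r(p) for p in perms]
    p_exact = np.mean([r >= res.r - 1e-12 for r in r_all])
    assert res.p_value == pytest.approx(p_exact, abs=1e-12)
    assert res.n_permutations == len(perms)


def test_anosim_rank_based_invariance_under_monotone_transform():
    dm = _separated_dm()
    transformed = DistanceMatrix(
        ids=dm.ids, matrix=np.sqrt(dm.matrix), metric="sqrt"
    )
    labels = ["a", "a", "b", "b", "a", "b"]
    r1 = anosim(dm, labels, n_perm=9, seed=1).r
    r2 = anosim(transformed, labels, n_perm=9, seed=1).r
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_anosim_null_mean_near_zero():
    rng = np.random.default_rng(4)
    coords = rng.normal(size=(12, 4))
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(
        ids=[f"s{i}" for i in range(12)], matrix=squareform(pdist(coords)), metric="e"
    )
    labels = ["a"] * 6 + ["b"] * 6
    rs = []
    for perm_seed in range(200):
        perm = np.random.default_rng(perm_seed).permutation(labels)
        rs.append(anosim(dm, perm, n_perm=1, seed=0).r)
    assert abs(np.mean(rs)) < 0.05


def test_anosim_input_validation():
    dm = _separated_dm()
    with pytest.raises(ValueError):
        anosim(dm, ["a"] * 6, n_perm=9)
    with pytest.raises(ValueError):
        anosim(dm, ["a", "b", "b", "b", "b", "b"], n_perm=9)


# -------------------------------------------------------------------- nmds

def _planar_dm(n=12, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(size=(n, 2))
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        ids=[f"s{i}" for i in range(n)], matrix=squareform(pdist(pts)), metric="e"
    ), pts


def test_nmds_planar_distances_embed_with_near_zero_stress():
    dm, _ = _planar_dm()
    res = nmds(dm, k=2, trymax=10, seed=0)
    assert res.stress < 1e-3


def test_nmds_stress_matches_independent_majorization(pytestconfig):
    """Stress on a small noisy fixture agrees with scikit-learn's
    independent nonmetric MDS (normalized stress-1) within 1e-3."""
    from sklearn.manifold import MDS

    rng = np.random.default_rng(5)
    pts = rng.normal(size=(8, 3))
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(
        ids=[f"s{i}" for i in range(8)], matrix=squareform(pdist(pts)), metric="e"
    )
    ours = nmds(dm, k=2, trymax=50, seed=0)
    oracle = MDS(
        n_components=2,
        metric=False,
        dissimilarity="precomputed",
        normalized_stress=True,
        n_init=50,
        max_iter=500,
        random_state=0,
    )
    oracle.fit(dm.matrix)
    assert ours.stress == pytest.approx(oracle.stress_, abs=1e-3)


def test_nmds_invariant_to_input_ordering():
    dm, pts = _planar_dm(n=10, seed=3)
    perm = np.random.default_rng(1).permutation(10)
    dm_perm = DistanceMatrix(
        ids=[dm.ids[i] for i in perm], matrix=dm.matrix[np.ix_(perm, perm)], metric="e"
    )
    res1 = nmds(dm, k=2, trymax=5, seed=0)
    res2 = nmds(dm_perm, k=2, trymax=5, seed=0)
    assert res1.stress == pytest.approx(res2.stress, abs=1e-6)


def test_nmds_stress_nonincreasing_with_dimension():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(10, 4))
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(
        ids=[f"s{i}" for i in range(10)], matrix=squareform(pdist(pts)), metric="e"
    )
    s1 = nmds(dm, k=1, trymax=20, seed=0).stress
    s2 = nmds(dm, k=2, trymax=20, seed=0).stress
    assert s2 <= s1 + 1e-6


def test_nmds_requires_four_samples():
    dm = DistanceMatrix(ids=["a", "b"], matrix=np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        nmds(dm, k=2)


# -------------------------------------------------------------------- ward

def _brute_force_ward_merges(points):
    """O(n^3) search: repeatedly merge the pair minimizing the Ward
    increase |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2."""
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            ca = points[list(a)].mean(axis=0)
            cb = points[list(b)].mean(axis=0)
            cost = len(a) * len(b) / (len(a) + len(b)) * ((ca - cb) ** 2).sum()
            if best is None or cost < best[0] - 1e-12:
                best = (cost, a, b)
        _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append(a | b)
    return merges


def _scipy_ward_merges(z, n):
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (i, j, _, _) in enumerate(z):
        merged = members[int(i)] | members[int(j)]
        members[n + step] = merged
        merges.append(merged)
    return merges


def test_ward_merge_order_matches_bruteforce_criterion():
    rng = np.random.default_rng(21)
    points = rng.normal(size=(8, 3))
    df = pd.DataFrame(points, index=[f"s{i}" for i in range(8)])
    res = ward_cluster(df, sites=["x"] * 8, n_clusters=2, transform=None)
    assert _scipy_ward_merges(res.linkage, 8) == _brute_force_ward_merges(points)


def test_ward_duplicate_samples_merge_first():
    points = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0], [9.0, 1.0]])
    df = pd.DataFrame(points, index=list("abcd"))
    res = ward_cluster(df, sites=["x"] * 4, n_clusters=2, transform=None)
    first = _scipy_ward_merges(res.linkage, 4)[0]
    assert first == frozenset([0, 2])


def test_ward_two_blobs_perfectly_pure():
    rng = np.random.default_rng(8)
    blob1 = rng.normal(0, 0.1, size=(10, 3))
    blob2 = rng.normal(8, 0.1, size=(10, 3))
    df = pd.DataFrame(np.vstack([blob1, blob2]), index=[f"s{i}" for i in range(20)])
    sites = ["siteA"] * 10 + ["siteB"] * 10
    res = ward_cluster(df, sites=sites, transform=None)
    assert set(res.purity.values()) == {1.0}
    assert set(res.majority_site.values()) == {"siteA", "siteB"}


def test_ward_rejects_k_above_n():
    df = pd.DataFrame(np.eye(3))
    with pytest.raises(ValueError):
        ward_cluster(df, sites=["a", "b", "c"], n_clusters=5, transform=None)


def test_newick_export_contains_all_leaves():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                      index=[f"s{i}" for i in range(5)])
    res = ward_cluster(df, sites=["x"] * 5, n_clusters=2, transform=None)
    nwk = linkage_to_newick(res.linkage, list(df.index))
    assert nwk.endswith(";")
    for leaf in df.index:
        assert leaf in nwk


# ----------------------------------------------------------- jaccard

def test_jaccard_identical_partitions():
    assert clustering_jaccard([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0


def test_jaccard_singletons_vs_one_cluster():
    assert clustering_jaccard([1, 2, 3, 4], [0, 0, 0, 0]) == 0.0


def test_jaccard_matches_hand_enumerated_pairs():
    a = [1, 1, 1, 2, 2, 3]
    b = [1, 1, 2, 2, 2, 3]
    # hand enumeration over the 15 pairs:
    # co-clustered in both: (0,1), (3,4)            -> n11 = 2
    # in a only: (0,2), (1,2)                       -> n10 = 2
    # in b only: (2,3), (2,4)                       -> n01 = 2
    assert clustering_jaccard(a, b) == pytest.approx(2 / 6)


def test_jaccard_needs_two_samples():
    with pytest.raises(ValueError):
        clustering_jaccard([1], [1])
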