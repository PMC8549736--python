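"""K-mer index, pseudoalignment, EM resolution, and normalization."""

import numpy as np
import pandas as pd
import pytest

from bgcbiogeo.quantify import (
    ClassCounts,
    abundance_filter,
    aggregate_to_bgc,
    build_index,
    em_quantify,
    encode_dna,
    finalize_counts,
    pseudoalign,
    pseudoalign_batch,
    quantify_sample,
    reverse_complement_codes,
    sanitize_sequences,
    size_factor_normalize,
)
from bgcbiogeo.tables import CountMatrix

from conftest import make_record

RNG = np.random.default_rng(42)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------- sanitize

def test_sanitize_pure_acgt_untouched():
    out, n = sanitize_sequences({"a": "ACGT"}, seed=1)
    assert out == {"a": "ACGT"} and n == 0


def test_sanitize_replaces_only_ambiguous_positions():
    out, n = sanitize_sequences({"a": "ACNT"}, seed=1)
    assert n == 1
    assert len(out["a"]) == 4
    assert out["a"][0] == "A" and out["a"][1] == "C" and out["a"][3] == "T"
    assert out["a"][2] in "ACGT"


def test_sanitize_counts_all_ambiguity_codes():
    seq = "ACGTRYSWKMN" + "ACGT"  # 7 IUPAC ambiguity characters
    _, n = sanitize_sequences({"a": seq}, seed=3)
    assert n == 7


def test_sanitize_rejects_empty_sequence():
    with pytest.raises(ValueError, match="rec1"):
        sanitize_sequences({"rec1": ""}, seed=1)


# ------------------------------------------------------------------- index

def test_single_31mer_target():
    seq = random_seq(31)
    index = build_index({"orf1": seq}, k=31)
    assert index.n_kmers == 1
    assert index.classes[index.kmer_class[0]] == (0,)
    assert index.effective_length.tolist() == [1]


def test_identical_targets_share_every_class():
    seq = random_seq(60)
    index = build_index({"a": seq, "b": seq}, k=31)
    assert all(index.classes[c] == (0, 1) for c in index.kmer_class)


def test_equivalence_classes_match_bruteforce_enumeration():
    """Class of every k-mer equals the brute-force set of targets whose
    substrings (either strand) contain it."""
    k = 31
    shared = random_seq(40)
    seqs = {
        "a": random_seq(25) + shared + random_seq(20),
        "b": shared + random_seq(33),
        "c": random_seq(50),
    }
    index = build_index(seqs, k=k)
    # brute-force oracle over all substrings
    oracle: dict[str, set[int]] = {}
    for tid, name in enumerate(index.target_ids):
        s = seqs[name]
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            canon = min(kmer, revcomp(kmer))
            oracle.setdefault(canon, set()).add(tid)
    assert index.n_kmers == len(oracle)
    for kmer, targets in oracle.items():
        code = int(
            np.asarray(
                [
                    sum(("ACGT".index(b)) << (2 * (k - 1 - i)) for i, b in enumerate(kmer))
                ],
                dtype=np.int64,
            )[0]
        )
        pos = int(np.searchsorted(index.kmers, code))
        assert index.kmers[pos] == code
        assert set(index.classes[index.kmer_class[pos]]) == targets


def test_index_json_roundtrip(tmp_path):
    seqs = {"a": random_seq(60), "b": random_seq(45)}
    index = build_index(seqs, k=31)
    path = tmp_path / "index.json"
    index.to_json(path)
    from bgcbiogeo.quantify import KmerIndex

    loaded = KmerIndex.from_json(path)
    assert loaded.k == index.k
    assert loaded.target_ids == index.target_ids
    assert np.array_equal(loaded.kmers, index.kmers)
    assert loaded.classes == index.classes
    read = seqs["a"][10:45]
    assert pseudoalign(read, loaded) == pseudoalign(read, index)


def test_short_target_skipped_with_warning():
    index = build_index({"short": random_seq(10), "ok": random_seq(40)}, k=31)
    assert index.skipped_targets == ["short"]
    assert index.target_ids == ["ok"]


# ------------------------------------------------------------ pseudoalign

@pytest.fixture(scope="module")
def toy_index():
    seqs = {"orfA": random_seq(200), "orfB": random_seq(180)}
    return build_index(seqs, k=31), seqs


def test_exact_substring_assigned_uniquely(toy_index):
    index, seqs = toy_index
    read = seqs["orfA"][37 : 37 + 80]
    assert pseudoalign(read, index) == frozenset({"orfA"})


def test_reverse_complement_assigned_identically(toy_index):
    index, seqs = toy_index
    read = seqs["orfB"][10:90]
    assert pseudoalign(revcomp(read), index) == frozenset({"orfB"})


def test_alien_read_unassigned(toy_index):
    index, _ = toy_index
    rng = np.random.default_rng(999)
    read = "".join(rng.choice(list("ACGT"), size=80))
    assert pseudoalign(read, index) is None


def test_read_shorter_than_k_unassigned(toy_index):
    index, _ = toy_index
    assert pseudoalign("ACGT", index) is None


def test_batch_matches_single_read_path(toy_index):
    index, seqs = toy_index
    reads = [
        seqs["orfA"][0:80],
        revcomp(seqs["orfA"][50:130]),
        seqs["orfB"][20:100],
        "".join(np.random.default_rng(1).choice(list("ACGT"), size=80)),
    ]
    codes = np.stack([encode_dna(r) for r in reads])
    cc = pseudoalign_batch(codes, index)
    assert cc.n_assigned == 3 and cc.n_unassigned == 1
    a_idx = index.target_ids.index("orfA")
    b_idx = index.target_ids.index("orfB")
    assert cc.counts == {(a_idx,): 2, (b_idx,): 1}


def test_strand_invariance_of_batch_counts(toy_index):
    """Reverse-complementing every read leaves all counts unchanged."""
    index, seqs = toy_index
    rng = np.random.default_rng(5)
    reads = []
    for _ in range(50):
        src = seqs["orfA"] if rng.random() < 0.5 else seqs["orfB"]
        start = rng.integers(0, len(src) - 80 + 1)
        reads.append(src[start : start + 80])
    codes = np.stack([encode_dna(r) for r in reads])
    fwd = pseudoalign_batch(codes, index)
    rc = pseudoalign_batch(reverse_complement_codes(codes), index)
    assert fwd.counts == rc.counts


# -------------------------------------------------------------------- EM

def _index_with_lengths(lengths):
    class FakeIndex:
        n_targets = len(lengths)
        effective_length = np.asarray(lengths)

    return FakeIndex()


def test_em_equals_direct_counting_for_singleton_classes():
    idx = _index_with_lengths([100, 100, 100])
    est = em_quantify({(0,): 5, (1,): 7, (2,): 2}, idx)
    assert np.allclose(est, [5, 7, 2])


def test_em_splits_symmetric_ambiguity_evenly():
    idx = _index_with_lengths([100, 100])
    est = em_quantify({(0, 1): 10}, idx)
    assert np.allclose(est, [5, 5])


def test_em_matches_gridsearch_likelihood_maximum():
    """Two-target toy: class {A}: 6 reads, class {A,B}: 4 reads.

    The EM fixed point must agree (to 1e-3 counts) with a grid search
    over the multinomial likelihood L(p) = p^6 * (p + (1-p))^4 = p^6,
    evaluated on the two-class data with equal effective lengths.
    """
    counts = {(0,): 6, (0, 1): 4}
    idx = _index_with_lengths([100, 100])
    est = em_quantify(counts, idx, max_iter=5000, tol=1e-9)
    # independent grid-search maximizer over p = P(read from A)
    grid = np.linspace(1e-6, 1 - 1e-6, 200001)
    loglik = 6 * np.log(grid) + 4 * np.log(grid + (1 - grid))
    p_best = grid[np.argmax(loglik)]
    expected_a = 6 + 4 * p_best / (p_best + (1 - p_best))
    assert est.sum() == pytest.approx(10.0, abs=1e-6)
    assert est[0] == pytest.approx(expected_a, abs=1e-3)


def test_em_loglikelihood_nondecreasing():
    rng = np.random.default_rng(11)
    idx = _index_with_lengths([50, 80, 120, 60])
    counts = {
        (0,): 10,
        (0, 1): 6,
        (1, 2): 9,
        (0, 2, 3): 4,
        (3,): 3,
    }
    _, logliks = em_quantify(counts, idx, return_loglik=True, tol=1e-12, max_iter=60)
    diffs = np.diff(logliks)
    assert (diffs >= -1e-9).all()


# --------------------------------------------------------------- aggregate

def test_aggregate_sums_orfs_to_bgc():
    rec = make_record("b1", ["nrps"], n_orfs=2)
    series = aggregate_to_bgc({"b1_orf0": 2.2, "b1_orf1": 3.3}, [rec])
    assert series["b1"] == pytest.approx(5.5)


def test_aggregate_fixture_matches_manual_sums():
    recs = [make_record(f"b{i}", ["nrps"], n_orfs=2) for i in range(3)]
    counts = {f"b{i}_orf{j}": 10 * i + j for i in range(3) for j in range(2)}
    series = aggregate_to_bgc(counts, recs)
    assert series.tolist() == [1, 21, 41]


def test_aggregate_rejects_orphan_orfs():
    rec = make_record("b1", ["nrps"], n_orfs=1)
    with pytest.raises(KeyError, match="ghost"):
        aggregate_to_bgc({"ghost_orf": 1.0}, [rec])


# ---------------------------------------------------------------- finalize

def test_finalize_rounds_pseudocounts_and_drops_undetected():
    samples = {
        "s1": pd.Series({"b1": 2.5, "b2": 0.0, "b3": 1.2}),
        "s2": pd.Series({"b1": 0.4, "b2": 0.0, "b3": 3.6}),
    }
    m = finalize_counts(samples)
    assert m.state == "pseudocounted"
    assert m.dropped_undetected == 1
    assert "b2" not in m.counts.index
    assert m.counts.loc["b1", "s1"] == 4  # 2.5 -> 3 -> +1
    assert m.counts.loc["b1", "s2"] == 1  # 0.4 -> 0 -> +1
    assert (m.counts.to_numpy() >= 1).all()


# --------------------------------------------------------------- normalize

def test_size_factors_track_depth_doubling():
    base = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
    m = CountMatrix(counts=base, state="pseudocounted")
    normalized = size_factor_normalize(m)
    s = normalized.size_factors
    assert s["s2"] / s["s1"] == pytest.approx(2.0)
    assert np.allclose(normalized.normalized["s1"], normalized.normalized["s2"])


def test_size_factors_all_equal_matrix():
    base = pd.DataFrame(np.full((4, 3), 7), columns=["s1", "s2", "s3"])
    m = CountMatrix(counts=base, state="pseudocounted")
    assert np.allclose(size_factor_normalize(m).size_factors, 1.0)


def test_size_factors_match_hand_computed_median_of_ratios():
    counts = pd.DataFrame(
        {"s1": [2, 4, 16], "s2": [4, 8, 2], "s3": [8, 2, 4]}, index=list("abc")
    )
    m = size_factor_normalize(CountMatrix(counts=counts, state="pseudocounted"))
    gm = np.exp(np.log(counts.to_numpy()).mean(axis=1))
    expected = np.median(counts.to_numpy() / gm[:, None], axis=0)
    assert np.allclose(m.size_factors, expected)


def test_duplicating_reads_scales_size_factor_proportionally():
    # the geometric-mean reference itself moves by 2^(1/n), so the
    # proportionality is approximate and tightens with sample count
    rng = np.random.default_rng(3)
    n_samples = 24
    base = rng.integers(1, 50, size=(30, n_samples))
    counts = pd.DataFrame(base, columns=[f"s{i}" for i in range(1, n_samples + 1)])
    doubled = counts.copy()
    doubled["s4"] = counts["s4"] * 2
    m1 = size_factor_normalize(CountMatrix(counts=counts, state="pseudocounted"))
    m2 = size_factor_normalize(CountMatrix(counts=doubled, state="pseudocounted"))
    ratio = m2.size_factors["s4"] / m1.size_factors["s4"]
    assert ratio == pytest.approx(2.0, rel=0.05)
    before = m1.normalized["s4"]
    after = m2.normalized["s4"]
    assert np.allclose(before, after, rtol=0.05)


def test_abundance_filter_strict_boundary():
    normalized = pd.DataFrame(
        {"s1": [50.0, 50.0, 10.0], "s2": [49.9, 50.0, 5.0]}, index=list("abc")
    )
    m = CountMatrix(
        counts=normalized.round().astype(int),
        state="normalized",
        normalized=normalized,
    )
    kept = abundance_filter(m, min_total=100.0)
    assert list(kept.normalized.index) == ["b"]  # 99.9 removed, 100.0 retained
    with pytest.raises(ValueError):
        abundance_filter(m, min_total=1e9)


# ------------------------------------------------------- end-to-end truth

def test_errorfree_unique_orfs_recover_truth_exactly():
    """With no errors, no background, and unique ORF sequences, the
    estimated ORF counts equal the generator's true read counts, and
    assigned + unassigned reads conserve the per-sample total."""
    from bgcbiogeo.synthetic_data import SyntheticConfig, generate_study

    config = SyntheticConfig(
        n_sites=2,
        samples_per_site=3,
        n_genomes=6,
        reads_per_sample=800,
        substitution_error_rate=0.0,
        background_fraction=0.0,
        planted_enrichment=[],
        seed=123,
    )
    study = generate_study(config)
    index = build_index(study.orf_seqs, k=31)
    for sample_id in study.metadata.index:
        batch = study.sample_reads(sample_id)
        est, cc = quantify_sample(batch.codes, index, tol=1e-9)
        assert cc.n_assigned + cc.n_unassigned == config.reads_per_sample
        truth = study.truth.true_orf_read_counts[sample_id]
        for tid, name in enumerate(index.target_ids):
            assert est[tid] == pytest.approx(truth.get(name, 0), abs=1e-6)
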