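"""Metagenome-to-BGC quantification by k-mer pseudoalignment.

Reads are assigned to biosynthetic-ORF targets without base-level
alignment: a length-31 canonical k-mer index maps every k-mer to the set
of targets containing it (its equivalence class), a read's class is the
intersection of the classes of its k-mers (k-mers absent from the index
are ignored, which tolerates isolated substitution errors), and
multi-mapping reads are resolved by a multinomial EM that distributes
each class's reads across member targets in proportion to their current
estimated abundance.  ORF-level estimates are then aggregated per BGC,
pseudocounted, and normalized with median-of-ratios size factors.

All heavy paths operate on 2-bit-encoded read matrices so that a full
synthetic study (hundreds of samples) quantifies in minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import BGCRecord
from .tables import CountMatrix

__all__ = [
    "KmerIndex",
    "ClassCounts",
    "encode_dna",
    "decode_dna",
    "reverse_complement_codes",
    "sanitize_sequences",
    "build_index",
    "pseudoalign",
    "pseudoalign_batch",
    "em_quantify",
    "quantify_sample",
    "aggregate_to_bgc",
    "finalize_counts",
    "size_factor_normalize",
    "abundance_filter",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_dna(seq: str) -> np.ndarray:
    """2-bit encode a DNA string (A=0, C=1, G=2, T=3; other bases 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis of a 2-bit code array."""
    return (codes[..., ::-1] ^ 3).astype(codes.dtype)


def _kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes along the last axis.

    Input may be 1-D (one sequence) or 2-D (a read batch, rows of equal
    length).  Positions containing a non-ACGT base propagate to invalid
    k-mers; use :func:`_valid_kmer_mask` to mask those out.
    """
    arr = np.atleast_2d(base_codes)
    n, length = arr.shape
    if length < k:
        raise ValueError(f"sequence length {length} < k={k}")
    mask = np.uint64((1 << (2 * k)) - 1)
    out = np.empty((n, length - k + 1), dtype=np.uint64)
    code = np.zeros(n, dtype=np.uint64)
    safe = np.where(arr > 3, 0, arr).astype(np.uint64)
    for j in range(length):
        code = ((code << np.uint64(2)) | safe[:, j]) & mask
        if j >= k - 1:
            out[:, j - k + 1] = code
    return out if base_codes.ndim == 2 else out[0]


def _valid_kmer_mask(base_codes: np.ndarray, k: int) -> np.ndarray:
    arr = np.atleast_2d(base_codes)
    bad = (arr > 3).astype(np.int32)
    cs = np.concatenate(
        [np.zeros((arr.shape[0], 1), dtype=np.int32), np.cumsum(bad, axis=1)], axis=1
    )
    window_bad = cs[:, k:] - cs[:, :-k]
    mask = window_bad == 0
    return mask if base_codes.ndim == 2 else mask[0]


def _canonical_kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (lexicographic min of strand pair) k-mer codes.

    The reverse-strand codes come from rolling over the reverse-
    complemented sequence: k-mer i of the forward strand is k-mer
    L-k-i of the reverse complement.
    """
    fwd = _kmer_codes(base_codes, k)
    rc_read = reverse_complement_codes(np.atleast_2d(base_codes))
    rc = _kmer_codes(rc_read, k)[..., ::-1]
    if base_codes.ndim == 1:
        rc = rc[0] if rc.ndim == 2 else rc
    return np.minimum(fwd, rc)


def sanitize_sequences(
    sequences: Mapping[str, str], seed: int
) -> tuple[dict[str, str], int]:
    """Replace non-ACGT characters by seeded pseudorandom bases.

    Returns the sanitized sequences and the total replacement count.
    ACGT positions are untouched; an empty sequence raises a
    ``ValueError`` naming the record.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    n_replaced = 0
    for name, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for record {name!r}")
        codes = encode_dna(seq)
        bad = codes > 3
        n_bad = int(bad.sum())
        if n_bad:
            codes = codes.copy()
            codes[bad] = rng.integers(0, 4, size=n_bad, dtype=np.uint8)
            n_replaced += n_bad
            out[name] = decode_dna(codes)
        else:
            out[name] = seq.upper()
    return out, n_replaced


@dataclass
class KmerIndex:
    """Canonical k-mer index over biosynthetic ORF targets.

    ``kmers`` is the sorted array of canonical k-mer integer codes;
    ``kmer_class[i]`` is the equivalence-class id of ``kmers[i]``; and
    ``classes[c]`` is the sorted tuple of target indices of class ``c``.
    """

    k: int
    target_ids: list[str]
    effective_length: np.ndarray
    kmers: np.ndarray
    kmer_class: np.ndarray
    classes: list[tuple[int, ...]]
    skipped_targets: list[str] = field(default_factory=list)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    def class_targets(self, class_id: int) -> tuple[int, ...]:
        return self.classes[class_id]

    def to_json(self, path) -> None:
        """Serialize the index to a JSON container."""
        import json

        with open(path, "w") as handle:
            json.dump(
                {
                    "k": self.k,
                    "target_ids": self.target_ids,
                    "effective_length": self.effective_length.tolist(),
                    "kmers": self.kmers.tolist(),
                    "kmer_class": self.kmer_class.tolist(),
                    "classes": [list(c) for c in self.classes],
                    "skipped_targets": self.skipped_targets,
                },
                handle,
            )

    @classmethod
    def from_json(cls, path) -> "KmerIndex":
        import json

        with open(path) as handle:
            data = json.load(handle)
        return cls(
            k=data["k"],
            target_ids=data["target_ids"],
            effective_length=np.asarray(data["effective_length"], dtype=np.int64),
            kmers=np.asarray(data["kmers"], dtype=np.int64),
            kmer_class=np.asarray(data["kmer_class"], dtype=np.int32),
            classes=[tuple(c) for c in data["classes"]],
            skipped_targets=data.get("skipped_targets", []),
        )


def build_index(sequences: Mapping[str, str], k: int = 31) -> KmerIndex:
    """Build the canonical k-mer index over sanitized ORF sequences.

    Sequences shorter than ``k`` are skipped with a warning; equivalence
    classes (sets of targets sharing a k-mer) are deduplicated.
    """
    target_ids: list[str] = []
    eff_len: list[int] = []
    code_chunks: list[np.ndarray] = []
    tid_chunks: list[np.ndarray] = []
    skipped: list[str] = []
    for name, seq in sequences.items():
        if len(seq) < k:
            logger.warning("target %s shorter than k=%d; skipped", name, k)
            skipped.append(name)
            continue
        tid = len(target_ids)
        target_ids.append(name)
        eff_len.append(len(seq) - k + 1)
        codes = _canonical_kmer_codes(encode_dna(seq), k)
        code_chunks.append(codes)
        tid_chunks.append(np.full(len(codes), tid, dtype=np.int64))
    if not target_ids:
        raise ValueError("no indexable sequences (all shorter than k)")
    all_codes = np.concatenate(code_chunks)
    all_tids = np.concatenate(tid_chunks)
    order = np.lexsort((all_tids, all_codes))
    all_codes = all_codes[order]
    all_tids = all_tids[order]
    boundaries = np.flatnonzero(np.diff(all_codes)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(all_codes)]])
    unique_codes = all_codes[starts].astype(np.int64)  # 62-bit codes: order-safe
    class_of: dict[tuple[int, ...], int] = {}
    classes: list[tuple[int, ...]] = []
    kmer_class = np.empty(len(unique_codes), dtype=np.int32)
    for i, (s, e) in enumerate(zip(starts, ends)):
        members = tuple(int(t) for t in np.unique(all_tids[s:e]))
        cid = class_of.get(members)
        if cid is None:
            cid = len(classes)
            class_of[members] = cid
            classes.append(members)
        kmer_class[i] = cid
    return KmerIndex(
        k=k,
        target_ids=target_ids,
        effective_length=np.asarray(eff_len, dtype=np.int64),
        kmers=unique_codes,
        kmer_class=kmer_class,
        classes=classes,
        skipped_targets=skipped,
    )


def pseudoalign(read: str, index: KmerIndex) -> Optional[frozenset[str]]:
    """Assign one read to its compatibility class of target ids.

    Returns the intersection of the equivalence classes of the read's
    canonical k-mers (k-mers absent from the index are ignored), or
    ``None`` (unassigned) when no k-mer hits the index, the intersection
    is empty, or the read is shorter than k.
    """
    codes = encode_dna(read)
    if len(codes) < index.k:
        logger.warning("read shorter than k=%d; unassigned", index.k)
        return None
    canon = _canonical_kmer_codes(codes, index.k).astype(np.int64)
    valid = _valid_kmer_mask(codes, index.k)
    result: Optional[set[int]] = None
    for code, ok in zip(canon, valid):
        if not ok:
            continue
        pos = int(np.searchsorted(index.kmers, code))
        if pos >= len(index.kmers) or index.kmers[pos] != code:
            continue
        members = set(index.classes[index.kmer_class[pos]])
        result = members if result is None else (result & members)
        if result is not None and not result:
            return None
    if result is None or not result:
        return None
    return frozenset(index.target_ids[t] for t in result)


@dataclass
class ClassCounts:
    """Pseudoalignment result for one sample.

    ``counts`` maps a sorted tuple of target indices (a compatibility
    class) to the number of reads assigned to it.
    """

    counts: dict[tuple[int, ...], int]
    n_assigned: int
    n_unassigned: int


def pseudoalign_batch(read_codes: np.ndarray, index: KmerIndex) -> ClassCounts:
    """Pseudoalign a batch of equal-length 2-bit-encoded reads.

    The fast path covers reads whose in-index k-mers all agree on one
    equivalence class (the overwhelming majority); the remainder fall
    back to explicit class-set intersection.
    """
    n_reads = read_codes.shape[0]
    if n_reads == 0:
        return ClassCounts(counts={}, n_assigned=0, n_unassigned=0)
    if read_codes.shape[1] < index.k:
        return ClassCounts(counts={}, n_assigned=0, n_unassigned=n_reads)
    canon = _canonical_kmer_codes(read_codes, index.k).astype(np.int64)
    valid = _valid_kmer_mask(read_codes, index.k)
    pos = np.searchsorted(index.kmers, canon)
    pos_c = np.minimum(pos, len(index.kmers) - 1)
    found = valid & (pos < len(index.kmers)) & (index.kmers[pos_c] == canon)
    cls = np.where(found, index.kmer_class[pos_c], -1).astype(np.int64)
    any_hit = found.any(axis=1)
    cls_max = cls.max(axis=1)
    sentinel = np.iinfo(np.int64).max
    cls_min = np.where(found, cls, sentinel).min(axis=1)
    uniform = any_hit & (cls_min == cls_max)
    counts: dict[tuple[int, ...], int] = {}
    if uniform.any():
        uc, n = np.unique(cls_min[uniform], return_counts=True)
        for cid, c in zip(uc, n):
            key = index.classes[int(cid)]
            counts[key] = counts.get(key, 0) + int(c)
    n_unassigned = int((~any_hit).sum())
    mixed_rows = np.flatnonzero(any_hit & ~uniform)
    for row in mixed_rows:
        hit_classes = np.unique(cls[row][found[row]])
        members: Optional[set[int]] = None
        for cid in hit_classes:
            s = set(index.classes[int(cid)])
            members = s if members is None else (members & s)
            if not members:
                break
        if not members:
            n_unassigned += 1
        else:
            key = tuple(sorted(members))
            counts[key] = counts.get(key, 0) + 1
    n_assigned = n_reads - n_unassigned
    return ClassCounts(counts=counts, n_assigned=n_assigned, n_unassigned=n_unassigned)


def em_quantify(
    class_counts: Mapping[tuple[int, ...], int],
    index: KmerIndex,
    max_iter: int = 200,
    tol: float = 1e-3,
    return_loglik: bool = False,
):
    """Resolve multi-mapping reads by multinomial EM.

    The model treats each read as a multinomial draw over targets with
    per-target probability proportional to ``theta_t * effective_length``
    (theta being per-base abundance), i.e. proportional to the expected
    read count ``n_t`` itself, and the observed data as counts over
    compatibility classes.  Iteration stops when the largest absolute
    change in any estimated count is below ``tol``.

    Returns the per-target estimated counts (summing to the number of
    assigned reads), plus the log-likelihood trajectory if requested.
    """
    n_targets = index.n_targets
    est = np.zeros(n_targets, dtype=float)
    if not class_counts:
        return (est, []) if return_loglik else est
    keys = list(class_counts.keys())
    class_sizes = np.array([len(k) for k in keys], dtype=np.int64)
    member_idx = np.concatenate([np.asarray(k, dtype=np.int64) for k in keys])
    member_class = np.repeat(np.arange(len(keys), dtype=np.int64), class_sizes)
    counts = np.array([class_counts[k] for k in keys], dtype=float)
    total = counts.sum()
    # initialize by splitting each class uniformly across its members
    np.add.at(est, member_idx, np.repeat(counts / class_sizes, class_sizes))
    logliks: list[float] = []
    for _ in range(max_iter):
        p = est / est.sum()
        p_member = p[member_idx]
        denom = np.bincount(member_class, weights=p_member, minlength=len(keys))
        if return_loglik:
            with np.errstate(divide="ignore"):
                logliks.append(float(np.sum(counts * np.log(denom))))
        safe = np.where(denom > 0, denom, 1.0)
        contrib = counts[member_class] * p_member / safe[member_class]
        new = np.bincount(member_idx, weights=contrib, minlength=n_targets)
        delta = np.abs(new - est).max()
        est = new
        if delta < tol:
            break
    # renormalize away any floating drift so counts sum to assigned reads
    est *= total / est.sum()
    return (est, logliks) if return_loglik else est


def quantify_sample(
    read_codes: np.ndarray,
    index: KmerIndex,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> tuple[np.ndarray, ClassCounts]:
    """Pseudoalign a read batch and EM-resolve it to per-ORF counts."""
    cc = pseudoalign_batch(read_codes, index)
    est = em_quantify(cc.counts, index, max_iter=max_iter, tol=tol)
    return est, cc


def aggregate_to_bgc(
    orf_counts: Mapping[str, float], catalog: Iterable[BGCRecord]
) -> pd.Series:
    """Sum per-ORF estimated counts into per-BGC estimated counts.

    Every ORF id in ``orf_counts`` must belong to exactly one BGC in the
    catalog; orphans raise a ``KeyError`` listing the offending ids.
    """
    orf_to_bgc: dict[str, str] = {}
    bgc_ids: list[str] = []
    for record in catalog:
        bgc_ids.append(record.bgc_id)
        for orf in record.orfs:
            orf_to_bgc[orf.orf_id] = record.bgc_id
    orphans = [oid for oid in orf_counts if oid not in orf_to_bgc]
    if orphans:
        raise KeyError(f"ORF ids not present in catalog: {sorted(orphans)[:10]}")
    sums = dict.fromkeys(bgc_ids, 0.0)
    for oid, value in orf_counts.items():
        sums[orf_to_bgc[oid]] += float(value)
    return pd.Series(sums, name="estimated_count")


def finalize_counts(sample_bgc_counts: Mapping[str, pd.Series]) -> CountMatrix:
    """Assemble per-sample BGC estimates into a pseudocounted matrix.

    BGCs with zero estimated count in every sample are dropped (and the
    drop count recorded); remaining estimates are rounded half away from
    zero and one pseudocount is added to every cell.
    """
    df = pd.DataFrame(sample_bgc_counts)  # rows: BGCs, columns: samples
    detected = df.sum(axis=1) > 0
    n_dropped = int((~detected).sum())
    if n_dropped:
        logger.info("dropping %d BGCs undetected in every sample", n_dropped)
    df = df.loc[detected]
    rounded = np.floor(df.to_numpy(dtype=float) + 0.5)  # half away from zero (x >= 0)
    pseudo = pd.DataFrame(
        rounded + 1.0, index=df.index, columns=df.columns
    ).astype(int)
    return CountMatrix(
        counts=pseudo, state="pseudocounted", dropped_undetected=n_dropped
    )


def size_factor_normalize(m: CountMatrix) -> CountMatrix:
    """Median-of-ratios size factors and normalized counts.

    ``s_j = median_i count[i, j] / geomean_j' count[i, j']``; the
    pseudocount guarantees strictly positive geometric means.
    """
    if m.state != "pseudocounted":
        raise ValueError("size_factor_normalize expects a pseudocounted matrix")
    counts = m.counts.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        logger.warning("single sample: size factor fixed at 1")
        s = np.ones(1)
    else:
        log_gm = np.mean(np.log(counts), axis=1, keepdims=True)
        ratios = counts / np.exp(log_gm)
        s = np.median(ratios, axis=0)
    size_factors = pd.Series(s, index=m.counts.columns, name="size_factor")
    normalized = m.counts / size_factors
    return CountMatrix(
        counts=m.counts,
        state="normalized",
        size_factors=size_factors,
        normalized=normalized,
        dropped_undetected=m.dropped_undetected,
    )


def abundance_filter(m: CountMatrix, min_total: float = 100.0) -> CountMatrix:
    """Drop BGCs with < ``min_total`` total normalized reads (strict)."""
    if m.state != "normalized":
        raise ValueError("abundance_filter expects a normalized matrix")
    assert m.normalized is not None
    keep = m.normalized.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError("abundance filter removed every BGC")
    return CountMatrix(
        counts=m.counts.loc[keep],
        state="normalized",
        size_factors=m.size_factors,
        normalized=m.normalized.loc[keep],
        dropped_undetected=m.dropped_undetected,
    )
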