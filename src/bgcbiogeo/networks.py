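"""BGC similarity networks and RiPP core-peptide identity networks.

The BGC network connects clusters whose domain-content distance falls
below a cutoff; connected components are gene cluster families (GCFs).
The distance blends three components computed from each cluster's
ordered protein-domain string: Jaccard similarity of domain sets (J),
adjacency-pair Jaccard (AI), and a domain copy-number similarity (DSS,
one minus the normalized L1 difference of copy-number vectors).

The peptide pipeline extracts short ORFs from RiPP-class clusters,
scores them with a deterministic rule-based precursor classifier (an
interface point: externally computed classifier scores can be supplied
instead), cleaves the leader at the last Gly-Gly motif in the first
two-thirds of the precursor, and connects core peptides whose global
BLOSUM62 alignment identity meets a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .catalog import BGCRecord, RIPP_SUBTYPES, categorize_type

__all__ = [
    "BgcNetwork",
    "PeptideRecord",
    "PeptideNetwork",
    "bgc_distance",
    "pairwise_bgc_distances",
    "build_bgc_network",
    "extract_precursor_orfs",
    "classify_precursor",
    "load_classifier_scores",
    "cleave_leader",
    "peptide_identity",
    "build_peptide_network",
]

logger = logging.getLogger(__name__)

_DEFAULT_WEIGHTS = (0.2, 0.05, 0.75)
_AA_SET = set("ACDEFGHIKLMNPQRSTVWY")
_RIPP_LIKE_TYPES = RIPP_SUBTYPES | {"bacteriocin"}


@dataclass
class BgcNetwork:
    graph: nx.Graph
    families: dict[str, int]

    @property
    def n_families(self) -> int:
        return len(set(self.families.values()))

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("source\ttarget\tdistance\n")
            for u, v, data in self.graph.edges(data=True):
                handle.write(f"{u}\t{v}\t{data['distance']:.6f}\n")


@dataclass
class PeptideRecord:
    orf_id: str
    bgc_id: str
    precursor: str
    classifier_score: float = 0.0
    ripp_class: Optional[str] = None
    leader: str = ""
    core: str = ""


@dataclass
class PeptideNetwork:
    graph: nx.Graph
    reference_matches: list[tuple[str, str, float]] = field(default_factory=list)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _adjacency_pairs(domains: Sequence[str]) -> set[tuple[str, str]]:
    return {(domains[i], domains[i + 1]) for i in range(len(domains) - 1)}


def _jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def bgc_distance(
    a: BGCRecord, b: BGCRecord, weights: tuple[float, float, float] = _DEFAULT_WEIGHTS
) -> float:
    """Domain-content distance in [0, 1] between two clusters.

    distance = 1 - (wJ*J + wA*AI + wD*DSS) with J the Jaccard of domain
    sets, AI the Jaccard of adjacent ordered domain pairs, and DSS one
    minus the Bray-Curtis-style normalized L1 difference of domain
    copy-number vectors.  Two clusters with no domains at all are
    maximally distant.
    """
    w_j, w_a, w_d = weights
    if abs(w_j + w_a + w_d - 1.0) > 1e-9:
        raise ValueError("distance component weights must sum to 1")
    dom_a = a.domains
    dom_b = b.domains
    if not dom_a and not dom_b:
        return 1.0
    j = _jaccard(set(dom_a), set(dom_b))
    ai = _jaccard(_adjacency_pairs(dom_a), _adjacency_pairs(dom_b))
    keys = set(dom_a) | set(dom_b)
    ca = {k: dom_a.count(k) for k in keys}
    cb = {k: dom_b.count(k) for k in keys}
    l1 = sum(abs(ca[k] - cb[k]) for k in keys)
    total = sum(ca[k] + cb[k] for k in keys)
    dss = 1.0 - l1 / total if total else 0.0
    return 1.0 - (w_j * j + w_a * ai + w_d * dss)


def pairwise_bgc_distances(
    catalog: Sequence[BGCRecord],
    weights: tuple[float, float, float] = _DEFAULT_WEIGHTS,
) -> np.ndarray:
    """Square matrix of pairwise cluster distances."""
    n = len(catalog)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bgc_distance(catalog[i], catalog[j], weights)
    return out


def build_bgc_network(
    catalog: Sequence[BGCRecord],
    distances: Optional[np.ndarray] = None,
    cutoff: float = 0.3,
    enriched_site: Optional[Mapping[str, str]] = None,
    median_log10_abundance: Optional[Mapping[str, float]] = None,
) -> BgcNetwork:
    """Gene-cluster-family network at a distance cutoff.

    Edges connect clusters at distance <= ``cutoff``; singletons remain
    as their own families.  Optional annotation maps (enriched site,
    median log10 normalized abundance) are attached to nodes; ids in an
    annotation map that are not in the catalog raise an error.
    """
    ids = [r.bgc_id for r in catalog]
    id_set = set(ids)
    for name, ann in (
        ("enriched_site", enriched_site),
        ("median_log10_abundance", median_log10_abundance),
    ):
        if ann is not None:
            unknown = sorted(set(ann) - id_set)
            if unknown:
                raise ValueError(f"{name} annotation for unknown BGCs: {unknown[:10]}")
    if distances is None:
        distances = pairwise_bgc_distances(catalog)
    graph = nx.Graph()
    for record in catalog:
        graph.add_node(
            record.bgc_id,
            genus=record.genus,
            category=categorize_type(record),
            enriched_site=(enriched_site or {}).get(record.bgc_id, ""),
            median_log10_abundance=float(
                (median_log10_abundance or {}).get(record.bgc_id, np.nan)
            ),
        )
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if distances[i, j] <= cutoff:
                graph.add_edge(ids[i], ids[j], distance=float(distances[i, j]))
    families = {}
    for fam_id, component in enumerate(nx.connected_components(graph)):
        for node in component:
            families[node] = fam_id
            graph.nodes[node]["family"] = fam_id
    return BgcNetwork(graph=graph, families=families)


def extract_precursor_orfs(
    catalog: Sequence[BGCRecord],
    orf_seqs: Mapping[str, str],
    max_nt: int = 450,
) -> list[PeptideRecord]:
    """Candidate precursor peptides from RiPP-class clusters.

    ORFs of at most ``max_nt`` nucleotides are taken from clusters
    categorized RiPP or Bacteriocin (or hybrids containing such a
    type), translated in frame 1 with the trailing stop trimmed; an ORF
    with an internal stop codon is dropped with a warning.
    """
    candidates: list[PeptideRecord] = []
    for record in catalog:
        category = categorize_type(record)
        ripp_like = category in {"RiPP", "Bacteriocin"} or (
            category == "Hybrid"
            and any(t in _RIPP_LIKE_TYPES for t in record.raw_types)
        )
        if not ripp_like:
            continue
        for orf in record.orfs:
            if orf.length_nt > max_nt:
                continue
            seq = orf_seqs.get(orf.orf_id)
            if seq is None:
                continue
            trimmed = seq[: len(seq) - len(seq) % 3]
            aa = str(Seq(trimmed).translate())
            if aa.endswith("*"):
                aa = aa[:-1]
            if "*" in aa:
                logger.warning("ORF %s has an internal stop; dropped", orf.orf_id)
                continue
            candidates.append(
                PeptideRecord(orf_id=orf.orf_id, bgc_id=record.bgc_id, precursor=aa)
            )
    return candidates


def classify_precursor(
    peptide: str,
    threshold: float = 0.75,
    external_score: Optional[float] = None,
    external_class: Optional[str] = None,
) -> tuple[float, Optional[str]]:
    """Deterministic rule-based precursor score and RiPP class.

    This is a transparent stand-in for a learned precursor classifier
    (the interface accepts externally computed scores): the score in
    [0, 1] combines precursor length within 20-120 aa (weight 0.45),
    Cys/Ser/Thr density in the C-terminal half relative to a 0.2
    reference (0.35), and presence of a Gly-Gly motif (0.20).  The
    class is assigned only when the score reaches ``threshold``:
    "lanthipeptide" when the C-terminal half has both Cys and Ser/Thr,
    otherwise "bacteriocin".
    """
    if len(peptide) < 10:
        raise ValueError("precursor must be at least 10 aa")
    bad = set(peptide) - _AA_SET
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    if external_score is not None:
        score = float(external_score)
        cls = external_class if score >= threshold else None
        return score, cls
    n = len(peptide)
    f_len = 1.0 if 20 <= n <= 120 else 0.0
    c_half = peptide[n // 2 :]
    density = sum(c_half.count(a) for a in "CST") / len(c_half)
    f_cst = min(1.0, density / 0.2)
    f_gg = 1.0 if "GG" in peptide else 0.0
    score = 0.45 * f_len + 0.35 * f_cst + 0.20 * f_gg
    if score < threshold:
        return score, None
    has_cys = "C" in c_half
    has_st = ("S" in c_half) or ("T" in c_half)
    ripp_class = "lanthipeptide" if has_cys and has_st else "bacteriocin"
    return score, ripp_class


def cleave_leader(peptide: str) -> tuple[str, str]:
    """Split a precursor into (leader, core).

    Cleavage is immediately after the last Gly-Gly motif whose end lies
    in the first two-thirds of the sequence; with no such motif the
    midpoint (floor(n/2)) is used.  leader + core always reconstructs
    the precursor.
    """
    n = len(peptide)
    limit = (2 * n) // 3
    cut = None
    for i in range(n - 2, -1, -1):
        if peptide[i : i + 2] == "GG" and i + 2 <= limit:
            cut = i + 2
            break
    if cut is None:
        cut = n // 2
    return peptide[:cut], peptide[cut:]


def load_classifier_scores(path) -> dict[str, tuple[float, Optional[str]]]:
    """Read externally computed precursor classifier scores.

    TSV columns: ``orf_id``, ``score`` (in [0, 1]), ``class`` (may be
    empty).  Returns ``orf_id -> (score, class)`` for use as the
    ``external_score``/``external_class`` inputs of
    :func:`classify_precursor`.
    """
    import csv

    out: dict[str, tuple[float, Optional[str]]] = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            score = float(row["score"])
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score for {row['orf_id']} outside [0, 1]")
            out[row["orf_id"]] = (score, row.get("class") or None)
    return out


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def peptide_identity(core_a: str, core_b: str) -> float:
    """Percent identity of a global BLOSUM62 alignment of two cores.

    Global mode penalizes terminal gaps, so the full length of both
    peptides is aligned (full-query coverage); identity is 100 x
    matches / alignment length.
    """
    if not core_a or not core_b:
        raise ValueError("cores must be nonempty")
    alignment = _aligner().align(core_a, core_b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def build_peptide_network(
    peptides: Iterable[PeptideRecord],
    references: Optional[Mapping[str, str]] = None,
    threshold: float = 75.0,
    enriched_site: Optional[Mapping[str, str]] = None,
    median_log10_abundance: Optional[Mapping[str, float]] = None,
) -> PeptideNetwork:
    """Core-peptide identity network with optional reference matching.

    Edges connect cores at identity >= ``threshold`` (75 by default;
    set 80 for the stricter rendering convention).  Reference peptides
    (name -> core sequence) are matched separately and recorded as
    (core orf id, reference name, identity) triples; with no references
    supplied that step is skipped with a warning.
    """
    peptides = [p for p in peptides if p.core]
    graph = nx.Graph()
    for p in peptides:
        graph.add_node(
            p.orf_id,
            bgc_id=p.bgc_id,
            core=p.core,
            ripp_class=p.ripp_class or "",
            enriched_site=(enriched_site or {}).get(p.bgc_id, ""),
            median_log10_abundance=float(
                (median_log10_abundance or {}).get(p.bgc_id, np.nan)
            ),
        )
    for i in range(len(peptides)):
        for j in range(i + 1, len(peptides)):
            ident = peptide_identity(peptides[i].core, peptides[j].core)
            if ident >= threshold:
                graph.add_edge(
                    peptides[i].orf_id, peptides[j].orf_id, identity=float(ident)
                )
    matches: list[tuple[str, str, float]] = []
    if references:
        for p in peptides:
            for name, ref_core in references.items():
                ident = peptide_identity(p.core, ref_core)
                if ident >= threshold:
                    matches.append((p.orf_id, name, float(ident)))
    else:
        logger.warning("no reference peptides supplied; reference matching skipped")
    return PeptideNetwork(graph=graph, reference_matches=matches)
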