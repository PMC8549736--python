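"""Synthetic aerodigestive-tract (ADT) metagenomic study generator.

Generates, with known ground truth, everything the downstream pipeline
consumes: a multi-genus BGC catalog with ORF sequences, per-site species
communities, shotgun reads drawn from ORF and background sequence, a
MetaPhlAn-style relative-abundance table, and sample metadata.

The statistical structure emulated:

* genomes carry 1-18 BGCs each (discrete uniform within the configured
  range), mirroring the per-genome BGC counts of common ADT genera;
* each body site has its own mean species profile — a shared log-normal
  backbone of species magnitudes multiplied by a bounded per-site tilt —
  and individual samples are Dirichlet draws around that profile;
* a configurable set of "planted" BGCs has its read-sampling weight
  multiplied by a known fold in one site, giving the enrichment caller a
  truth set to recover;
* reads are uniformly placed substrings of ORFs (strand chosen
  uniformly, per-base substitution errors) or, with probability
  ``background_fraction``, substrings of genome-specific non-BGC
  background sequence, exercising the quantifier's unassigned path.

Every sample has its own RNG stream derived from the global seed and the
sample id, so samples are reproducible independently and in parallel.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import BGCRecord, OrfRecord
from .quantify import decode_dna, encode_dna, reverse_complement_codes
from .tables import TaxaTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ReadBatch",
    "ReadSimulator",
    "SITE_POOL",
    "generate_catalog",
    "generate_communities",
    "simulate_sample_reads",
    "generate_study",
    "SyntheticStudy",
]

logger = logging.getLogger(__name__)

#: Body-site name pool, most-sampled sites first (the first four are the
#: deeply sampled sites used for enrichment calling).
SITE_POOL = (
    "buccal_mucosa",
    "tongue_dorsum",
    "external_naris",
    "gingiva",
    "palatine_tonsil",
    "saliva",
    "throat",
    "hard_palate",
    "nasal_cavity",
)

_GENUS_POOL = (
    "Streptococcus",
    "Corynebacterium",
    "Staphylococcus",
    "Neisseria",
    "Prevotella",
    "Fusobacterium",
    "Capnocytophaga",
    "Aggregatibacter",
    "Actinomyces",
    "Cutibacterium",
    "Rothia",
    "Veillonella",
)

_HABITATS = ("Nasal", "Nasal,Oral", "Oral", "NonOralRef", "Skin", "Unassigned", "Vaginal")
_HABITAT_P = (0.10, 0.10, 0.35, 0.25, 0.10, 0.05, 0.05)

# Raw antiSMASH-style single types with sampling weights shaped like the
# observed category composition of ADT catalogs (bacteriocins and RiPPs
# most common, a long tail of rarer classes).
_RAW_TYPES = (
    ("bacteriocin", 0.22),
    ("lantipeptide", 0.06),
    ("sactipeptide", 0.03),
    ("thiopeptide", 0.02),
    ("nrps", 0.12),
    ("terpene", 0.11),
    ("arylpolyene", 0.08),
    ("t1pks", 0.03),
    ("t3pks", 0.02),
    ("resorcinol", 0.03),
    ("siderophore", 0.06),
    ("hserlactone", 0.03),
    ("ectoine", 0.01),
    ("phosphonate", 0.01),
    ("butyrolactone", 0.01),
    ("ladderane", 0.08),
    ("phenazine", 0.09),
)
_HYBRID_P = 0.07

# Domain vocabularies keyed by raw type: BGCs of the same type share a
# pool, so the domain-based similarity network recovers type families.
_DOMAIN_POOLS = {
    "bacteriocin": ["DUF95", "Bacteriocin_IIc", "ABC_membrane", "Peptidase_C39"],
    "lantipeptide": ["LANC_like", "Lant_dehydr_N", "Lant_dehydr_C", "Peptidase_C39"],
    "sactipeptide": ["rSAM", "SPASM", "DUF95"],
    "thiopeptide": ["YcaO", "Lant_dehydr_N", "rSAM", "thio_amide"],
    "nrps": ["Condensation", "AMP-binding", "PCP", "Thioesterase", "Epimerization"],
    "terpene": ["Terpene_synth_C", "SQHop_cyclase_N", "polyprenyl_synt"],
    "arylpolyene": ["APE_KS", "FabH", "ACP", "Thioesterase"],
    "t1pks": ["PKS_KS", "PKS_AT", "PKS_KR", "ACP", "PKS_DH"],
    "t3pks": ["Chal_sti_synt_N", "Chal_sti_synt_C"],
    "resorcinol": ["Chal_sti_synt_N", "DarB_like"],
    "siderophore": ["IucA_IucC", "FhuF", "Lys_monoox"],
    "hserlactone": ["Autoind_synth"],
    "ectoine": ["Ectoine_synth", "Aminotran_3"],
    "phosphonate": ["PEP_mutase", "Ppd_decarb"],
    "butyrolactone": ["AfsA"],
    "ladderane": ["FabH", "ACP", "Ladderane_KS"],
    "phenazine": ["PHZA_PHZB", "Pyridox_ox", "EsV-1-7"],
}
_SHARED_DOMAINS = ["MFS_transporter", "ABC_tran", "HTH_regulator", "Methyltransf_12"]

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA = "ACDEFGHIKLMNPQRSTVWY"
_CORE_AA = "CSTGA"  # Cys/Ser/Thr-rich core alphabet

#: Auto-planting defaults: planted clusters per site and their fold.
PLANTED_PER_SITE = 3
PLANTED_FOLD = 8.0



@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study; defaults define the standard
    desk-scale study: 4 sites x 250 samples at 10^4 reads per sample."""

    n_sites: int = 4
    samples_per_site: int = 250
    n_genomes: int = 40
    bgc_per_genome_range: tuple[int, int] = (1, 6)
    orf_per_bgc_range: tuple[int, int] = (2, 4)
    orf_length_range: tuple[int, int] = (300, 1200)
    reads_per_sample: int = 10_000
    read_length: int = 100
    substitution_error_rate: float = 0.001
    background_fraction: float = 0.10
    planted_enrichment: Optional[list[tuple[str, str, float]]] = None
    dirichlet_concentration: float = 300.0
    #: Bound, in log2 units, of the per-site per-species abundance tilt.
    #: The default keeps natural between-site species folds below
    #: 2^(2*0.8) ~ 3, so the only >= 4-fold BGC differences are planted.
    site_tilt_log2: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "samples_per_site", "n_genomes", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("bgc_per_genome_range", "orf_per_bgc_range", "orf_length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a nonempty positive range")
        if self.orf_length_range[0] < 3:
            raise ValueError("orf_length_range must start at >= 3 nt")
        for name in ("substitution_error_rate", "background_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.site_tilt_log2 < 0:
            raise ValueError("site_tilt_log2 must be nonnegative")
        if self.planted_enrichment is not None:
            for site, bgc, fold in self.planted_enrichment:
                if fold < 1:
                    raise ValueError(f"planted fold for {bgc} in {site} must be >= 1")

    @property
    def sites(self) -> list[str]:
        if self.n_sites <= len(SITE_POOL):
            return list(SITE_POOL[: self.n_sites])
        extra = [f"site_{i}" for i in range(len(SITE_POOL), self.n_sites)]
        return list(SITE_POOL) + extra


@dataclass
class GroundTruth:
    """Known generating quantities of a synthetic study."""

    true_site_species_profiles: dict[str, dict[str, float]]
    true_enriched_bgcs: dict[str, dict[str, float]]
    true_orf_read_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    background_reads: dict[str, int] = field(default_factory=dict)

    def validate(self, catalog: Sequence[BGCRecord]) -> None:
        for site, profile in self.true_site_species_profiles.items():
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"profile for {site} sums to {total}, not 1")
        bgc_ids = {r.bgc_id for r in catalog}
        for site, planted in self.true_enriched_bgcs.items():
            missing = set(planted) - bgc_ids
            if missing:
                raise ValueError(f"planted BGCs absent from catalog: {missing}")

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "true_site_species_profiles": self.true_site_species_profiles,
                    "true_enriched_bgcs": self.true_enriched_bgcs,
                    "true_orf_read_counts": self.true_orf_read_counts,
                    "background_reads": self.background_reads,
                },
                handle,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)


@dataclass
class ReadBatch:
    """A simulated sample's reads as 2-bit codes plus read ids."""

    sample_id: str
    ids: list[str]
    codes: np.ndarray

    def sequences(self) -> list[str]:
        return [decode_dna(row) for row in self.codes]

    def write_fastq(self, handle) -> None:
        qual = "I" * self.codes.shape[1]
        for rid, row in zip(self.ids, self.codes):
            handle.write(f"@{rid}\n{decode_dna(row)}\n+\n{qual}\n")


def _sample_seed(seed: int, sample_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return decode_dna(rng.integers(0, 4, size=length, dtype=np.uint8))


def _precursor_orf(rng: np.random.Generator) -> tuple[str, int]:
    """A RiPP precursor ORF: Met leader ending in Gly-Gly, then a
    Cys/Ser/Thr-rich core, reverse-translated with a stop codon."""
    leader_len = int(rng.integers(12, 26))
    core_len = int(rng.integers(15, 31))
    leader = "M" + "".join(rng.choice(list(_AA), size=leader_len - 3)) + "GG"
    core = "".join(rng.choice(list(_CORE_AA), size=core_len))
    nt = "".join(_CODON[aa] for aa in leader + core) + "TAA"
    return nt, len(nt)


def generate_catalog(
    config: SyntheticConfig,
) -> tuple[list[BGCRecord], dict[str, str]]:
    """Generate the genome/BGC catalog and ORF nucleotide sequences.

    Deterministic for a fixed ``config.seed``.  Each genome carries a
    discrete-uniform number of BGCs from ``bgc_per_genome_range``; RiPP
    and bacteriocin clusters additionally carry one short precursor ORF
    so the peptide pipeline has real substrate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0]))
    raw_names = [t for t, _ in _RAW_TYPES]
    raw_p = np.array([w for _, w in _RAW_TYPES])
    raw_p = raw_p / raw_p.sum()
    catalog: list[BGCRecord] = []
    orf_seqs: dict[str, str] = {}
    ripp_like = {"bacteriocin", "lantipeptide", "sactipeptide", "thiopeptide"}
    bgc_counter = 0
    lo_b, hi_b = config.bgc_per_genome_range
    lo_o, hi_o = config.orf_per_bgc_range
    lo_l, hi_l = config.orf_length_range
    for g in range(config.n_genomes):
        genome_id = f"g{g:03d}"
        genus = _GENUS_POOL[g % len(_GENUS_POOL)]
        species = f"{genus} sp. HMT-{g:03d}"
        habitat = str(rng.choice(_HABITATS, p=_HABITAT_P))
        n_bgc = int(rng.integers(lo_b, hi_b + 1))
        for _ in range(n_bgc):
            bgc_id = f"bgc{bgc_counter:04d}"
            bgc_counter += 1
            if rng.random() < _HYBRID_P:
                raw_types = list(rng.choice(raw_names, size=2, replace=False, p=raw_p))
            else:
                raw_types = [str(rng.choice(raw_names, p=raw_p))]
            pool = list(_DOMAIN_POOLS[raw_types[0]]) + _SHARED_DOMAINS
            orfs: list[OrfRecord] = []
            n_orf = int(rng.integers(lo_o, hi_o + 1))
            has_precursor = raw_types[0] in ripp_like
            for j in range(n_orf):
                orf_id = f"{bgc_id}_orf{j}"
                if has_precursor and j == 0:
                    seq, length = _precursor_orf(rng)
                else:
                    length = int(rng.integers(lo_l // 3, hi_l // 3 + 1)) * 3
                    seq = _random_dna(rng, length)
                n_dom = int(rng.integers(1, 4))
                domains = list(rng.choice(pool, size=min(n_dom, len(pool)), replace=False))
                biosynthetic = bool(rng.random() < 0.92) or (has_precursor and j == 0)
                orfs.append(
                    OrfRecord(
                        orf_id=orf_id,
                        length_nt=length,
                        biosynthetic=biosynthetic,
                        domain_string=domains,
                    )
                )
                orf_seqs[orf_id] = seq
            catalog.append(
                BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=genome_id,
                    genus=genus,
                    species=species,
                    habitat=habitat,
                    raw_types=raw_types,
                    contig_edge=bool(rng.random() < 0.05),
                    orfs=orfs,
                )
            )
    return catalog, orf_seqs


def _resolve_planting(
    config: SyntheticConfig,
    catalog: Sequence[BGCRecord],
    backbone: np.ndarray,
    genome_ids: list[str],
    rng: np.random.Generator,
) -> dict[str, dict[str, float]]:
    """Planted (site, bgc, fold) entries; auto-chosen when unspecified.

    Auto-planting draws ``PLANTED_PER_SITE`` clusters per site at
    ``PLANTED_FOLD``, restricted to genomes in the upper half of the
    backbone magnitude so the planted signal is observable at the
    simulated depth, with no cluster planted in two sites.
    """
    sites = config.sites
    if config.planted_enrichment is not None:
        out: dict[str, dict[str, float]] = {s: {} for s in sites}
        bgc_ids = {r.bgc_id for r in catalog}
        for site, bgc, fold in config.planted_enrichment:
            if site not in out:
                raise ValueError(f"planted site {site!r} not among {sites}")
            if bgc not in bgc_ids:
                raise ValueError(f"planted BGC {bgc!r} not in catalog")
            out[site][bgc] = float(fold)
        return out
    magnitude = dict(zip(genome_ids, backbone))
    cutoff = float(np.median(backbone))
    candidates = [
        r.bgc_id
        for r in catalog
        if magnitude[r.genome_id] >= cutoff
        and sum(orf.biosynthetic for orf in r.orfs) >= 1
    ]
    per_site = min(PLANTED_PER_SITE, max(1, len(candidates) // max(1, len(sites))))
    chosen = rng.choice(
        len(candidates), size=min(len(candidates), per_site * len(sites)), replace=False
    )
    out = {s: {} for s in sites}
    for i, idx in enumerate(chosen):
        out[sites[i % len(sites)]][candidates[int(idx)]] = PLANTED_FOLD
    return out


def generate_communities(
    config: SyntheticConfig, catalog: Sequence[BGCRecord]
) -> tuple[pd.DataFrame, TaxaTable, GroundTruth]:
    """Per-site species profiles, per-sample abundances, and metadata.

    Site mean profiles combine a shared log-normal(0, 1) backbone of
    species magnitudes with a bounded uniform per-site tilt (at most
    about 3-fold between any two sites), renormalized to sum to one.
    Each sample is a Dirichlet draw centered on its site profile with
    concentration ``dirichlet_concentration``, taken from the sample's
    own RNG stream.
    """
    catalog = list(catalog)
    if not catalog:
        raise ValueError("catalog must be nonempty")
    genome_ids: list[str] = []
    species_names: list[str] = []
    for record in catalog:
        if record.genome_id not in genome_ids:
            genome_ids.append(record.genome_id)
            species_names.append(record.species)
    if not species_names:
        raise ValueError("no species in catalog")
    n_species = len(species_names)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1]))
    backbone = rng.lognormal(mean=0.0, sigma=1.0, size=n_species)
    sites = config.sites
    profiles: dict[str, np.ndarray] = {}
    for site in sites:
        tilt = rng.uniform(-config.site_tilt_log2, config.site_tilt_log2, size=n_species)
        weights = backbone * np.exp2(tilt)
        profiles[site] = weights / weights.sum()
    planted = _resolve_planting(config, catalog, backbone, genome_ids, rng)
    rows = []
    abundances = {}
    for site_idx, site in enumerate(sites):
        for j in range(config.samples_per_site):
            sample_id = f"{site}_s{j:04d}"
            subject_id = f"subj{j:04d}"
            rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject_id,
                    "visit": site_idx + 1,
                    "site": site,
                    "total_reads": config.reads_per_sample,
                }
            )
            srng = np.random.default_rng(
                _sample_seed(config.seed, sample_id).spawn(2)[0]
            )
            alpha = config.dirichlet_concentration * profiles[site]
            abundances[sample_id] = srng.dirichlet(alpha)
    metadata = pd.DataFrame(rows).set_index("sample_id")
    taxa_df = pd.DataFrame.from_dict(abundances, orient="index", columns=species_names)
    taxa_df = taxa_df.loc[metadata.index]
    taxa = TaxaTable(abundances=taxa_df, total_reads=metadata["total_reads"])
    truth = GroundTruth(
        true_site_species_profiles={
            site: dict(zip(species_names, profiles[site])) for site in sites
        },
        true_enriched_bgcs=planted,
    )
    truth.validate(catalog)
    return metadata, taxa, truth


class ReadSimulator:
    """Vectorized shotgun-read simulator over a fixed catalog.

    Precomputes the concatenated 2-bit ORF sequence pool, per-ORF
    sampling weights, and per-genome background sequences (random DNA
    generated once per genome) so per-sample simulation is array work.
    """

    def __init__(
        self,
        catalog: Sequence[BGCRecord],
        orf_seqs: dict[str, str],
        config: SyntheticConfig,
    ) -> None:
        self.config = config
        self.catalog = list(catalog)
        read_len = config.read_length
        if read_len < 31:
            raise ValueError("read_length must be >= 31")
        self.genome_ids: list[str] = []
        self.species_by_genome: dict[str, str] = {}
        for record in self.catalog:
            if record.genome_id not in self.species_by_genome:
                self.genome_ids.append(record.genome_id)
                self.species_by_genome[record.genome_id] = record.species
        genome_index = {g: i for i, g in enumerate(self.genome_ids)}
        orf_ids: list[str] = []
        orf_genome: list[int] = []
        orf_bgc: list[str] = []
        lengths: list[int] = []
        chunks: list[np.ndarray] = []
        for record in self.catalog:
            for orf in record.orfs:
                seq = orf_seqs[orf.orf_id]
                if len(seq) < read_len:
                    logger.warning(
                        "ORF %s shorter than read length; skipped from sampling",
                        orf.orf_id,
                    )
                    continue
                orf_ids.append(orf.orf_id)
                orf_genome.append(genome_index[record.genome_id])
                orf_bgc.append(record.bgc_id)
                lengths.append(len(seq))
                chunks.append(encode_dna(seq))
        if not orf_ids:
            raise ValueError("no ORF is at least one read length long")
        self.orf_ids = orf_ids
        self.orf_genome = np.asarray(orf_genome)
        self.orf_bgc = orf_bgc
        self.orf_len = np.asarray(lengths, dtype=np.int64)
        self.pool = np.concatenate(chunks)
        self.offsets = np.concatenate([[0], np.cumsum(self.orf_len)])[:-1]
        genome_total = np.zeros(len(self.genome_ids))
        np.add.at(genome_total, self.orf_genome, self.orf_len.astype(float))
        self.len_share = self.orf_len / genome_total[self.orf_genome]
        # genome-specific background pools, generated once per genome
        bg_len = max(2000, read_len * 20)
        bg_chunks = []
        for g, gid in enumerate(self.genome_ids):
            brng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed & 0x7FFFFFFF, 2, zlib.crc32(gid.encode())]
                )
            )
            bg_chunks.append(brng.integers(0, 4, size=bg_len, dtype=np.uint8))
        self.background = np.stack(bg_chunks)
        self._fold_cache: dict[str, np.ndarray] = {}

    def _site_folds(self, site: str, truth: GroundTruth) -> np.ndarray:
        if site not in self._fold_cache:
            folds = np.ones(len(self.orf_ids))
            planted = truth.true_enriched_bgcs.get(site, {})
            for i, bgc in enumerate(self.orf_bgc):
                if bgc in planted:
                    folds[i] = planted[bgc]
            self._fold_cache[site] = folds
        return self._fold_cache[site]

    def simulate(
        self,
        sample_id: str,
        site: str,
        species_abundance: pd.Series,
        truth: GroundTruth,
    ) -> ReadBatch:
        """Simulate one sample's reads and record its ground truth."""
        config = self.config
        n = config.reads_per_sample
        read_len = config.read_length
        rng = np.random.default_rng(_sample_seed(config.seed, sample_id).spawn(2)[1])
        ra = np.array(
            [
                float(species_abundance.get(self.species_by_genome[g], 0.0))
                for g in self.genome_ids
            ]
        )
        if ra.sum() <= 0:
            raise ValueError(f"sample {sample_id}: no catalog species has abundance")
        ra = ra / ra.sum()
        is_bg = rng.random(n) < config.background_fraction
        n_bg = int(is_bg.sum())
        n_orf = n - n_bg
        codes = np.empty((n, read_len), dtype=np.uint8)
        # background reads: genome by relative abundance, uniform placement
        if n_bg:
            bg_genomes = rng.choice(len(self.genome_ids), size=n_bg, p=ra)
            max_start = self.background.shape[1] - read_len + 1
            starts = rng.integers(0, max_start, size=n_bg)
            cols = starts[:, None] + np.arange(read_len)
            codes[is_bg] = self.background[bg_genomes[:, None], cols]
        # BGC reads: ORF with weight RA x length share x planted fold
        orf_counts = np.zeros(len(self.orf_ids), dtype=np.int64)
        if n_orf:
            weights = ra[self.orf_genome] * self.len_share * self._site_folds(site, truth)
            total = weights.sum()
            if total <= 0:
                raise ValueError(f"sample {sample_id}: all ORF sampling weights zero")
            orf_idx = rng.choice(len(self.orf_ids), size=n_orf, p=weights / total)
            starts = self.offsets[orf_idx] + rng.integers(
                0, self.orf_len[orf_idx] - read_len + 1
            )
            codes[~is_bg] = self.pool[starts[:, None] + np.arange(read_len)]
            orf_counts = np.bincount(orf_idx, minlength=len(self.orf_ids))
        # uniform strand
        flip = rng.random(n) < 0.5
        codes[flip] = reverse_complement_codes(codes[flip])
        # per-base substitution errors (always to a different base)
        if config.substitution_error_rate > 0:
            err = rng.random((n, read_len)) < config.substitution_error_rate
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                codes[err] = (codes[err] + shift) % 4
        truth.true_orf_read_counts[sample_id] = {
            self.orf_ids[i]: int(c) for i, c in enumerate(orf_counts) if c
        }
        truth.background_reads[sample_id] = n_bg
        ids = [f"{sample_id}_r{i}" for i in range(n)]
        return ReadBatch(sample_id=sample_id, ids=ids, codes=codes)


def simulate_sample_reads(
    sample_id: str,
    site: str,
    taxa: TaxaTable,
    catalog: Sequence[BGCRecord],
    orf_seqs: dict[str, str],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> ReadBatch:
    """One-shot convenience wrapper around :class:`ReadSimulator`."""
    simulator = ReadSimulator(catalog, orf_seqs, config)
    return simulator.simulate(
        sample_id, site, taxa.abundances.loc[sample_id], truth
    )


@dataclass
class SyntheticStudy:
    """A fully generated study, ready for quantification."""

    config: SyntheticConfig
    catalog: list[BGCRecord]
    orf_seqs: dict[str, str]
    metadata: pd.DataFrame
    taxa: TaxaTable
    truth: GroundTruth
    simulator: ReadSimulator

    def sample_reads(self, sample_id: str) -> ReadBatch:
        site = self.metadata.loc[sample_id, "site"]
        return self.simulator.simulate(
            sample_id, site, self.taxa.abundances.loc[sample_id], self.truth
        )


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate catalog, communities, and a ready read simulator."""
    catalog, orf_seqs = generate_catalog(config)
    metadata, taxa, truth = generate_communities(config, catalog)
    simulator = ReadSimulator(catalog, orf_seqs, config)
    return SyntheticStudy(
        config=config,
        catalog=catalog,
        orf_seqs=orf_seqs,
        metadata=metadata,
        taxa=taxa,
        truth=truth,
        simulator=simulator,
    )
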