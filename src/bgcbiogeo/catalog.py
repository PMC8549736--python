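"""BGC catalog data model and summarization.

A catalog is a list of :class:`BGCRecord` objects, one per predicted
biosynthetic gene cluster (BGC), each carrying the genome it came from,
the eHOMD-style habitat label of that genome, the raw antiSMASH-style
type string(s), and its ordered open reading frames (ORFs).

The summarization logic reproduces the standard bookkeeping for such a
catalog: habitat labels partition genomes into aerodigestive-tract (ADT)
colonizers versus environmental reference bacteria, raw cluster types
roll up into thirteen product categories (with multi-type records called
hybrids), and per-category counts are tabulated with one-decimal
percentages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "OrfRecord",
    "BGCRecord",
    "CategorySummary",
    "ADT_HABITATS",
    "ENVIRONMENT_HABITATS",
    "CATEGORIES",
    "load_catalog",
    "write_catalog",
    "classify_source",
    "categorize_type",
    "summarize_categories",
    "filter_nonbiosynthetic_orfs",
]

#: eHOMD habitat labels treated as aerodigestive-tract colonizers.
ADT_HABITATS = frozenset({"Nasal", "Nasal,Oral", "Oral"})
#: eHOMD habitat labels treated as environmental reference bacteria.
ENVIRONMENT_HABITATS = frozenset({"NonOralRef", "Skin", "Unassigned", "Vaginal"})

#: Raw antiSMASH-style subtypes that roll up into the RiPP category.
RIPP_SUBTYPES = frozenset(
    {
        "cyanobactin",
        "glycocin",
        "lantipeptide",
        "lassopeptide",
        "linaridin",
        "microcin",
        "proteusin",
        "sactipeptide",
        "thiopeptide",
    }
)
#: Raw subtypes that roll up into the PKS category.
PKS_SUBTYPES = frozenset(
    {"otherks", "resorcinol", "t1pks", "t2pks", "t3pks", "transatpks"}
)

_SINGLE_TYPE_MAP = {
    "bacteriocin": "Bacteriocin",
    "nrps": "NRPS",
    "terpene": "Terpene",
    "arylpolyene": "Aryl Polyene",
    "siderophore": "Siderophore",
    "hserlactone": "HSL",
    "ectoine": "Ectoine",
    "phosphonate": "Phosphonate",
    "butyrolactone": "Butyrolactone",
}

#: The thirteen product categories, in canonical display order.
CATEGORIES = (
    "Bacteriocin",
    "RiPP",
    "NRPS",
    "Terpene",
    "Aryl Polyene",
    "PKS",
    "Siderophore",
    "HSL",
    "Ectoine",
    "Phosphonate",
    "Butyrolactone",
    "Hybrid",
    "Other",
)

_CATALOG_COLUMNS = [
    "bgc_id",
    "genome_id",
    "genus",
    "species",
    "habitat",
    "raw_types",
    "contig_edge",
    "orf_id",
    "length_nt",
    "biosynthetic",
    "domain_string",
]


@dataclass
class OrfRecord:
    """One ORF within a BGC."""

    orf_id: str
    length_nt: int
    biosynthetic: bool = True
    domain_string: list[str] = field(default_factory=list)
    sequence_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_nt < 3:
            raise ValueError(f"ORF {self.orf_id}: length_nt must be >= 3")
        if self.sequence_ref is None:
            self.sequence_ref = self.orf_id


@dataclass
class BGCRecord:
    """One predicted cluster with its ordered ORFs."""

    bgc_id: str
    genome_id: str
    genus: str
    species: str
    habitat: str
    raw_types: list[str]
    contig_edge: bool = False
    orfs: list[OrfRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.raw_types:
            raise ValueError(f"BGC {self.bgc_id}: raw_types must be nonempty")
        if self.habitat not in ADT_HABITATS | ENVIRONMENT_HABITATS:
            raise ValueError(
                f"BGC {self.bgc_id}: unknown habitat {self.habitat!r}"
            )

    @property
    def domains(self) -> list[str]:
        """All domains of all ORFs, in gene then domain order."""
        out: list[str] = []
        for orf in self.orfs:
            out.extend(orf.domain_string)
        return out


@dataclass
class CategorySummary:
    """Per-category ADT / environment counts with a Total row."""

    table: pd.DataFrame

    def row(self, category: str) -> pd.Series:
        return self.table.loc[category]


def classify_source(record: BGCRecord) -> str:
    """Return ``"ADT"`` or ``"Environment"`` from the habitat label."""
    if record.habitat in ADT_HABITATS:
        return "ADT"
    return "Environment"


def categorize_type(record: BGCRecord) -> str:
    """Map a record's raw type string(s) to one of the 13 categories.

    Records carrying two or more raw types are hybrids (antiSMASH merges
    adjacent clusters into one composite record); a single raw type is
    mapped through the subtype tables, with ``Other`` as the catch-all.
    """
    if len(record.raw_types) >= 2:
        return "Hybrid"
    raw = record.raw_types[0]
    if raw in RIPP_SUBTYPES:
        return "RiPP"
    if raw in PKS_SUBTYPES:
        return "PKS"
    return _SINGLE_TYPE_MAP.get(raw, "Other")


def _percent_half_up(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (22.1 for 862/3895)."""
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_categories(catalog: Iterable[BGCRecord]) -> CategorySummary:
    """Tabulate per-category ADT/environment counts and total percents."""
    catalog = list(catalog)
    if not catalog:
        raise ValueError("cannot summarize an empty catalog")
    counts = {cat: {"ADT": 0, "Environment": 0} for cat in CATEGORIES}
    for record in catalog:
        counts[categorize_type(record)][classify_source(record)] += 1
    grand_total = len(catalog)
    rows = []
    for cat in CATEGORIES:
        adt = counts[cat]["ADT"]
        env = counts[cat]["Environment"]
        total = adt + env
        rows.append(
            {
                "category": cat,
                "adt_count": adt,
                "environment_count": env,
                "total_count": total,
                "total_percent": _percent_half_up(total, grand_total),
            }
        )
    rows.append(
        {
            "category": "Total",
            "adt_count": sum(r["adt_count"] for r in rows),
            "environment_count": sum(r["environment_count"] for r in rows),
            "total_count": grand_total,
            "total_percent": 100.0,
        }
    )
    table = pd.DataFrame(rows).set_index("category")
    return CategorySummary(table=table)


def filter_nonbiosynthetic_orfs(
    catalog: Iterable[BGCRecord],
) -> tuple[list[BGCRecord], list[str]]:
    """Drop ORFs flagged nonbiosynthetic; drop (and report) emptied BGCs.

    Returns the filtered catalog and the ids of BGCs that lost every ORF
    (mirroring clusters discarded when all their genes turn out to be
    housekeeping genes commonly co-located with BGCs).
    """
    kept: list[BGCRecord] = []
    dropped: list[str] = []
    for record in catalog:
        orfs = [orf for orf in record.orfs if orf.biosynthetic]
        if orfs:
            kept.append(
                BGCRecord(
                    bgc_id=record.bgc_id,
                    genome_id=record.genome_id,
                    genus=record.genus,
                    species=record.species,
                    habitat=record.habitat,
                    raw_types=list(record.raw_types),
                    contig_edge=record.contig_edge,
                    orfs=orfs,
                )
            )
        else:
            dropped.append(record.bgc_id)
    return kept, dropped


def load_catalog(path) -> list[BGCRecord]:
    """Read a catalog TSV (one row per ORF) into BGC records.

    Rows sharing a ``bgc_id`` must be contiguous; ORF order follows row
    order. A ``bgc_id`` reappearing after a different BGC, or an unknown
    habitat value, raises a ``ValueError`` naming the offending row.
    """
    records: list[BGCRecord] = []
    seen: set[str] = set()
    current: Optional[BGCRecord] = None
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(_CATALOG_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"catalog file missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            bgc_id = row["bgc_id"]
            habitat = row["habitat"]
            if habitat not in ADT_HABITATS | ENVIRONMENT_HABITATS:
                raise ValueError(
                    f"line {lineno}: unknown habitat {habitat!r} for BGC {bgc_id}"
                )
            orf = OrfRecord(
                orf_id=row["orf_id"],
                length_nt=int(row["length_nt"]),
                biosynthetic=row["biosynthetic"] == "1",
                domain_string=[d for d in row["domain_string"].split(";") if d],
            )
            if current is not None and current.bgc_id == bgc_id:
                current.orfs.append(orf)
                continue
            if bgc_id in seen:
                raise ValueError(
                    f"line {lineno}: duplicate bgc_id {bgc_id!r} "
                    "(rows of one BGC must be contiguous)"
                )
            seen.add(bgc_id)
            current = BGCRecord(
                bgc_id=bgc_id,
                genome_id=row["genome_id"],
                genus=row["genus"],
                species=row["species"],
                habitat=habitat,
                raw_types=[t for t in row["raw_types"].split(";") if t],
                contig_edge=row["contig_edge"] == "1",
                orfs=[orf],
            )
            records.append(current)
    return records


def write_catalog(catalog: Iterable[BGCRecord], path) -> None:
    """Write a catalog to the one-row-per-ORF TSV schema."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_CATALOG_COLUMNS)
        for record in catalog:
            for orf in record.orfs:
                writer.writerow(
                    [
                        record.bgc_id,
                        record.genome_id,
                        record.genus,
                        record.species,
                        record.habitat,
                        ";".join(record.raw_types),
                        "1" if record.contig_edge else "0",
                        orf.orf_id,
                        orf.length_nt,
                        "1" if orf.biosynthetic else "0",
                        ";".join(orf.domain_string),
                    ]
                )
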