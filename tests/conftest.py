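"""Shared fixtures: hand-built catalogs and a session-scale synthetic study."""

from __future__ import annotations

import logging

import pytest

from bgcbiogeo.catalog import BGCRecord, OrfRecord

logging.getLogger("bgcbiogeo").setLevel(logging.ERROR)

# Per-category (ADT, environment) BGC counts of a published-scale ADT
# catalog survey; used to exercise the summarization bookkeeping at
# realistic magnitudes.
PUBLISHED_SCALE_COUNTS = {
    "Bacteriocin": (610, 252),
    "RiPP": (241, 202),
    "NRPS": (129, 356),
    "Terpene": (150, 296),
    "Aryl Polyene": (211, 99),
    "PKS": (105, 197),
    "Siderophore": (100, 138),
    "HSL": (11, 106),
    "Ectoine": (0, 27),
    "Phosphonate": (0, 18),
    "Butyrolactone": (9, 5),
    "Hybrid": (60, 213),
    "Other": (106, 254),
}

# One representative raw type string per category (Hybrid needs two).
CATEGORY_RAW_TYPES = {
    "Bacteriocin": ["bacteriocin"],
    "RiPP": ["lantipeptide"],
    "NRPS": ["nrps"],
    "Terpene": ["terpene"],
    "Aryl Polyene": ["arylpolyene"],
    "PKS": ["t1pks"],
    "Siderophore": ["siderophore"],
    "HSL": ["hserlactone"],
    "Ectoine": ["ectoine"],
    "Phosphonate": ["phosphonate"],
    "Butyrolactone": ["butyrolactone"],
    "Hybrid": ["nrps", "t1pks"],
    "Other": ["ladderane"],
}


def make_record(
    bgc_id: str,
    raw_types: list[str],
    habitat: str = "Oral",
    n_orfs: int = 1,
    domains: list[str] | None = None,
    genus: str = "Streptococcus",
) -> BGCRecord:
    orfs = [
        OrfRecord(orf_id=f"{bgc_id}_orf{i}", length_nt=300, domain_string=domains or [])
        for i in range(n_orfs)
    ]
    return BGCRecord(
        bgc_id=bgc_id,
        genome_id=f"genome_{bgc_id}",
        genus=genus,
        species=f"{genus} sp.",
        habitat=habitat,
        raw_types=raw_types,
        orfs=orfs,
    )


def build_count_catalog(counts: dict[str, tuple[int, int]]) -> list[BGCRecord]:
    """A catalog with prescribed per-category ADT/environment counts."""
    catalog = []
    i = 0
    for category, (n_adt, n_env) in counts.items():
        raw = CATEGORY_RAW_TYPES[category]
        for habitat, n in (("Oral", n_adt), ("Skin", n_env)):
            for _ in range(n):
                catalog.append(make_record(f"b{i:05d}", list(raw), habitat=habitat))
                i += 1
    return catalog


@pytest.fixture(scope="session")
def published_scale_catalog():
    return build_count_catalog(PUBLISHED_SCALE_COUNTS)


@pytest.fixture(scope="session")
def default_study():
    """The standard desk-scale study (4 sites x 250 samples), generated
    once per session; reads are simulated lazily per sample."""
    from bgcbiogeo.synthetic_data import SyntheticConfig, generate_study

    return generate_study(SyntheticConfig(seed=20260920))


@pytest.fixture(scope="session")
def small_study():
    """A light study for integration-style tests."""
    from bgcbiogeo.synthetic_data import SyntheticConfig, generate_study

    config = SyntheticConfig(
        n_sites=2,
        samples_per_site=12,
        n_genomes=10,
        reads_per_sample=1500,
        seed=7,
    )
    return generate_study(config)
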