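"""End-to-end pipeline orchestration with file-based stage isolation.

Each stage reads its inputs from files in the run directory and writes
its outputs (plus an entry in the JSON run manifest) back there, so any
stage can be rerun independently and two runs with the same
configuration and seed produce identical tabular outputs.  Stages, in
dependency order: simulate, summarize, quantify, diversity, community,
enrich, ancom, network.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancom import ancom_filter, ancom_w, estimated_taxon_counts
from .catalog import (
    categorize_type,
    filter_nonbiosynthetic_orfs,
    load_catalog,
    summarize_categories,
    write_catalog,
)
from .community import (
    anosim,
    bray_curtis,
    clustering_jaccard,
    linkage_to_newick,
    nmds,
    species_filter,
    ward_cluster,
)
from .diversity import diversity_regression, kruskal_dunn, shannon_metrics, sign_test
from .enrichment import nb_wald_one_vs_rest, select_enrichment_sites
from .networks import (
    build_bgc_network,
    build_peptide_network,
    classify_precursor,
    cleave_leader,
    extract_precursor_orfs,
    pairwise_bgc_distances,
)
from .quantify import (
    abundance_filter,
    aggregate_to_bgc,
    build_index,
    finalize_counts,
    quantify_sample,
    sanitize_sequences,
    size_factor_normalize,
)
from .synthetic_data import GroundTruth, ReadSimulator, SyntheticConfig
from .tables import TaxaTable

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "summarize",
    "quantify",
    "diversity",
    "community",
    "enrich",
    "ancom",
    "network",
)


@dataclass
class PipelineConfig:
    """Run configuration: synthetic block, stage toggles, thresholds."""

    outdir: Path
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    min_fold: float = 4.0
    max_padj: float = 1e-8
    anosim_permutations: int = 999
    nmds_trymax: int = 20
    nmds_max_samples: int = 250
    network_cutoff: float = 0.3
    identity_threshold: float = 75.0
    min_total_normalized: float = 100.0
    min_site_samples: int = 200
    classifier_threshold: float = 0.75
    ancom_min_sample_total: int = 10_000
    ancom_min_prevalence: int = 10
    ancom_min_taxon_total: int = 1_000
    species_min_ra: float = 0.001
    species_min_prevalence: int = 25

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.network_cutoff <= 1:
            raise ValueError("network_cutoff must be in (0, 1]")
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in [0, 100]")
        # the pipeline seed overrides the synthetic block's seed so one
        # flag controls every source of randomness
        object.__setattr__(self.synthetic, "seed", self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        synth = raw.pop("synthetic", {})
        if "planted_enrichment" in synth and synth["planted_enrichment"] is not None:
            synth["planted_enrichment"] = [
                tuple(entry) for entry in synth["planted_enrichment"]
            ]
        for key, value in synth.items():
            if key.endswith("_range"):
                synth[key] = tuple(value)
        raw.update(overrides)
        raw["synthetic"] = SyntheticConfig(**synth)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _require(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream artifacts {missing} "
            f"in {outdir} (run the producing stage first)"
        )


def _stage_simulate(cfg: PipelineConfig) -> dict:
    from .synthetic_data import generate_catalog, generate_communities

    catalog, orf_seqs = generate_catalog(cfg.synthetic)
    write_catalog(catalog, cfg.outdir / "catalog.tsv")
    with open(cfg.outdir / "orfs.fasta", "w") as handle:
        for name, seq in orf_seqs.items():
            handle.write(f">{name}\n{seq}\n")
    metadata, taxa, truth = generate_communities(cfg.synthetic, catalog)
    metadata.to_csv(cfg.outdir / "metadata.tsv", sep="\t")
    taxa.to_tsv(cfg.outdir / "taxa.tsv")
    truth.to_json(cfg.outdir / "truth.json")
    return {"n_bgcs": len(catalog), "n_orfs": len(orf_seqs), "n_samples": len(metadata)}


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _stage_summarize(cfg: PipelineConfig) -> dict:
    _require(cfg.outdir, "summarize", "catalog.tsv")
    catalog = load_catalog(cfg.outdir / "catalog.tsv")
    summary = summarize_categories(catalog)
    summary.table.to_csv(cfg.outdir / "category_summary.tsv", sep="\t")
    filtered, dropped = filter_nonbiosynthetic_orfs(catalog)
    return {
        "n_bgcs": len(catalog),
        "n_bgcs_after_orf_filter": len(filtered),
        "dropped_empty_bgcs": len(dropped),
    }


def _stage_quantify(cfg: PipelineConfig) -> dict:
    _require(
        cfg.outdir, "quantify", "catalog.tsv", "orfs.fasta", "metadata.tsv",
        "taxa.tsv", "truth.json",
    )
    catalog = load_catalog(cfg.outdir / "catalog.tsv")
    orf_seqs = _read_fasta(cfg.outdir / "orfs.fasta")
    metadata = pd.read_csv(cfg.outdir / "metadata.tsv", sep="\t", index_col="sample_id")
    taxa = TaxaTable.from_tsv(cfg.outdir / "taxa.tsv", total_reads=metadata["total_reads"])
    truth = GroundTruth.from_json(cfg.outdir / "truth.json")
    biosynthetic, _ = filter_nonbiosynthetic_orfs(catalog)
    keep = {orf.orf_id for r in biosynthetic for orf in r.orfs}
    clean, n_replaced = sanitize_sequences(
        {k: v for k, v in orf_seqs.items() if k in keep}, seed=cfg.seed
    )
    index = build_index(clean, k=31)
    simulator = ReadSimulator(catalog, orf_seqs, cfg.synthetic)
    per_sample: dict[str, pd.Series] = {}
    assigned = {}
    for sample_id, row in metadata.iterrows():
        batch = simulator.simulate(
            sample_id, row["site"], taxa.abundances.loc[sample_id], truth
        )
        est, cc = quantify_sample(batch.codes, index)
        orf_counts = dict(zip(index.target_ids, est))
        per_sample[sample_id] = aggregate_to_bgc(orf_counts, biosynthetic)
        assigned[sample_id] = cc.n_assigned
    matrix = finalize_counts(per_sample)
    matrix = size_factor_normalize(matrix)
    (matrix.counts - 1).to_csv(cfg.outdir / "raw_counts.tsv", sep="\t")
    matrix.to_tsv(cfg.outdir / "normalized_counts.tsv", cfg.outdir / "size_factors.tsv")
    pd.Series(assigned, name="assigned_reads").to_csv(
        cfg.outdir / "assigned_reads.tsv", sep="\t", index_label="sample_id"
    )
    truth.to_json(cfg.outdir / "truth.json")  # now includes realized read counts
    return {
        "n_targets": index.n_targets,
        "n_kmers": index.n_kmers,
        "replaced_ambiguous_nt": n_replaced,
        "dropped_undetected_bgcs": matrix.dropped_undetected,
    }


def _load_counts(cfg: PipelineConfig, stage: str):
    _require(cfg.outdir, stage, "raw_counts.tsv", "normalized_counts.tsv", "metadata.tsv")
    raw = pd.read_csv(cfg.outdir / "raw_counts.tsv", sep="\t", index_col=0)
    normalized = pd.read_csv(cfg.outdir / "normalized_counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(cfg.outdir / "metadata.tsv", sep="\t", index_col="sample_id")
    return raw, normalized, metadata


def _stage_diversity(cfg: PipelineConfig) -> dict:
    raw, _, metadata = _load_counts(cfg, "diversity")
    _require(cfg.outdir, "diversity", "taxa.tsv")
    taxa = TaxaTable.from_tsv(cfg.outdir / "taxa.tsv", total_reads=metadata["total_reads"])
    rows = []
    for sample_id in metadata.index:
        sp = shannon_metrics(taxa.abundances.loc[sample_id])
        bgc_vec = raw[sample_id]
        if bgc_vec.sum() > 0:
            bg = shannon_metrics(bgc_vec)
            h_bgc, s_bgc, e_bgc = bg.shannon, bg.richness, bg.equitability
        else:
            h_bgc, s_bgc, e_bgc = np.nan, 0, None
        rows.append(
            {
                "sample_id": sample_id,
                "site": metadata.loc[sample_id, "site"],
                "shannon_species": sp.shannon,
                "richness_species": sp.richness,
                "equitability_species": sp.equitability,
                "shannon_bgc": h_bgc,
                "richness_bgc": s_bgc,
                "equitability_bgc": e_bgc,
            }
        )
    div = pd.DataFrame(rows).set_index("sample_id")
    div.to_csv(cfg.outdir / "diversity.tsv", sep="\t")
    stats_out: dict = {}
    complete = div.dropna(subset=["shannon_species", "shannon_bgc"])
    for level in ("species", "bgc"):
        groups = {
            site: g[f"shannon_{level}"].to_numpy()
            for site, g in complete.groupby("site")
        }
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            res = kruskal_dunn(groups)
            res.dunn.to_csv(cfg.outdir / f"dunn_{level}.tsv", sep="\t", index=False)
            stats_out[f"kruskal_{level}"] = {
                "H": res.statistic,
                "p": res.p_value,
                "epsilon_squared": res.epsilon_squared,
                "letters": res.letters,
            }
    s, p = sign_test(complete["shannon_bgc"], complete["shannon_species"])
    stats_out["sign_test_bgc_gt_species"] = {"S": s, "p": p, "n": len(complete)}
    reg = diversity_regression(
        complete["shannon_species"], complete["shannon_bgc"], complete["site"]
    )
    reg.to_csv(cfg.outdir / "diversity_regression.tsv", sep="\t")
    with open(cfg.outdir / "diversity_stats.json", "w") as handle:
        json.dump(stats_out, handle, indent=2)
    return {"n_samples": len(div)}


def _bgc_proportions(normalized: pd.DataFrame) -> pd.DataFrame:
    props = normalized / normalized.sum(axis=0)
    return props.T  # samples x BGCs


def _stage_community(cfg: PipelineConfig) -> dict:
    _, normalized, metadata = _load_counts(cfg, "community")
    _require(cfg.outdir, "community", "taxa.tsv")
    taxa = TaxaTable.from_tsv(cfg.outdir / "taxa.tsv", total_reads=metadata["total_reads"])
    filtered = species_filter(
        taxa, min_ra=cfg.species_min_ra, min_prevalence=cfg.species_min_prevalence
    )
    sp_profiles = filtered.abundances
    nonzero = sp_profiles.sum(axis=1) > 0
    sp_profiles = sp_profiles.loc[nonzero]
    sites_sp = metadata.loc[sp_profiles.index, "site"]
    from .tables import CountMatrix

    norm_matrix = CountMatrix(
        counts=normalized.round().astype(int).clip(lower=0),
        state="normalized",
        normalized=normalized,
    )
    norm_matrix = abundance_filter(norm_matrix, cfg.min_total_normalized)
    bgc_props = _bgc_proportions(norm_matrix.normalized)
    sites_bgc = metadata.loc[bgc_props.index, "site"]
    results: dict = {}
    rng = np.random.default_rng(cfg.seed)
    for label, profiles, sites in (
        ("species", sp_profiles, sites_sp),
        ("bgc", bgc_props, sites_bgc),
    ):
        dm = bray_curtis(profiles)
        res = anosim(
            dm, sites.to_numpy(), n_perm=cfg.anosim_permutations,
            seed=int(rng.integers(2**31)),
        )
        results[f"anosim_{label}"] = {
            "R": res.r, "p": res.p_value, "permutations": res.n_permutations,
        }
        if dm.n > cfg.nmds_max_samples:
            pick = np.sort(
                rng.choice(dm.n, size=cfg.nmds_max_samples, replace=False)
            )
            sub = bray_curtis(profiles.iloc[pick])
        else:
            sub = dm
        nm = nmds(sub, k=2, trymax=cfg.nmds_trymax, seed=int(rng.integers(2**31)))
        results[f"nmds_{label}"] = {"stress": nm.stress, "n": sub.n}
        pd.DataFrame(
            nm.coordinates, index=sub.ids, columns=["NMDS1", "NMDS2"]
        ).to_csv(cfg.outdir / f"nmds_{label}.tsv", sep="\t", index_label="sample_id")
    ward_bgc = ward_cluster(norm_matrix.normalized.T, sites_bgc)
    # Hellinger (square-root) transform for relative abundances: a log
    # transform would let the many exact zeros dominate the distances
    ward_sp = ward_cluster(sp_profiles, sites_sp, transform=np.sqrt)
    common = ward_bgc.labels.index.intersection(ward_sp.labels.index)
    results["ward_bgc_purity"] = {str(k): v for k, v in ward_bgc.purity.items()}
    results["clustering_jaccard"] = clustering_jaccard(
        ward_sp.labels.loc[common], ward_bgc.labels.loc[common]
    )
    ward_bgc.labels.to_csv(cfg.outdir / "ward_clusters_bgc.tsv", sep="\t")
    with open(cfg.outdir / "ward_bgc.nwk", "w") as handle:
        handle.write(linkage_to_newick(ward_bgc.linkage, list(ward_bgc.labels.index)))
    with open(cfg.outdir / "community_stats.json", "w") as handle:
        json.dump(results, handle, indent=2)
    return {"n_species_after_filter": sp_profiles.shape[1], "n_bgcs_after_filter": bgc_props.shape[1]}


def _stage_enrich(cfg: PipelineConfig) -> dict:
    _, normalized, metadata = _load_counts(cfg, "enrich")
    from .tables import CountMatrix

    matrix = CountMatrix(
        counts=normalized.round().astype(int).clip(lower=0),
        state="normalized",
        normalized=normalized,
    )
    sites = select_enrichment_sites(metadata, cfg.min_site_samples)
    frames = []
    for site in sites:
        frames.append(
            nb_wald_one_vs_rest(
                matrix, metadata, site, min_fold=cfg.min_fold, max_padj=cfg.max_padj
            )
        )
    if not frames:
        logger.warning("no site reaches %d samples; enrichment skipped", cfg.min_site_samples)
        return {"n_sites": 0}
    out = pd.concat(frames)
    out.to_csv(cfg.outdir / "enrichment.tsv", sep="\t")
    return {"n_sites": len(sites), "n_enriched": int(out["enriched"].sum())}


def _stage_ancom(cfg: PipelineConfig) -> dict:
    _require(cfg.outdir, "ancom", "taxa.tsv", "metadata.tsv")
    metadata = pd.read_csv(cfg.outdir / "metadata.tsv", sep="\t", index_col="sample_id")
    taxa = TaxaTable.from_tsv(cfg.outdir / "taxa.tsv", total_reads=metadata["total_reads"])
    sites = select_enrichment_sites(metadata, cfg.min_site_samples)
    if len(sites) < 2:
        sites = list(metadata["site"].unique())[:2]
    site_a, site_b = sites[:2]
    counts = estimated_taxon_counts(taxa)
    pair_samples = metadata.index[metadata["site"].isin([site_a, site_b])]
    filtered = ancom_filter(
        counts.loc[pair_samples],
        min_sample_total=cfg.ancom_min_sample_total,
        min_prevalence=cfg.ancom_min_prevalence,
        min_taxon_total=cfg.ancom_min_taxon_total,
    )
    result = ancom_w(filtered, metadata.loc[filtered.index, "site"])
    result.insert(0, "site_b", site_b)
    result.insert(0, "site_a", site_a)
    result.to_csv(cfg.outdir / "ancom.tsv", sep="\t")
    return {
        "site_pair": [site_a, site_b],
        "n_taxa_tested": len(result),
        "n_differential": int(result["differential"].sum()),
    }


def _stage_network(cfg: PipelineConfig) -> dict:
    _require(cfg.outdir, "network", "catalog.tsv", "orfs.fasta", "normalized_counts.tsv")
    catalog = load_catalog(cfg.outdir / "catalog.tsv")
    orf_seqs = _read_fasta(cfg.outdir / "orfs.fasta")
    normalized = pd.read_csv(cfg.outdir / "normalized_counts.tsv", sep="\t", index_col=0)
    detected = [r for r in catalog if r.bgc_id in set(normalized.index)]
    enriched_site: dict[str, str] = {}
    enrichment_path = cfg.outdir / "enrichment.tsv"
    if enrichment_path.exists():
        enr = pd.read_csv(enrichment_path, sep="\t")
        for row in enr[enr["enriched"]].itertuples():
            enriched_site.setdefault(row.bgc_id, row.site)
    medians = np.log10(normalized).median(axis=1).to_dict()
    distances = pairwise_bgc_distances(detected)
    net = build_bgc_network(
        detected,
        distances,
        cutoff=cfg.network_cutoff,
        enriched_site=enriched_site,
        median_log10_abundance=medians,
    )
    net.to_edge_tsv(cfg.outdir / "bgc_network_edges.tsv")
    net.to_graphml(cfg.outdir / "bgc_network.graphml")
    candidates = extract_precursor_orfs(catalog, orf_seqs)
    kept = []
    for p in candidates:
        try:
            score, ripp_class = classify_precursor(
                p.precursor, threshold=cfg.classifier_threshold
            )
        except ValueError:
            continue
        if ripp_class is None:
            continue
        p.classifier_score = score
        p.ripp_class = ripp_class
        p.leader, p.core = cleave_leader(p.precursor)
        kept.append(p)
    pep_net = build_peptide_network(
        kept,
        threshold=cfg.identity_threshold,
        enriched_site=enriched_site,
        median_log10_abundance=medians,
    )
    pep_net.to_graphml(cfg.outdir / "peptide_network.graphml")
    pd.DataFrame(
        [
            {
                "orf_id": p.orf_id,
                "bgc_id": p.bgc_id,
                "score": p.classifier_score,
                "ripp_class": p.ripp_class,
                "leader": p.leader,
                "core": p.core,
            }
            for p in kept
        ]
    ).to_csv(cfg.outdir / "core_peptides.tsv", sep="\t", index=False)
    return {
        "n_bgc_nodes": net.graph.number_of_nodes(),
        "n_bgc_edges": net.graph.number_of_edges(),
        "n_families": net.n_families,
        "n_core_peptides": len(kept),
        "n_peptide_edges": pep_net.graph.number_of_edges(),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "summarize": _stage_summarize,
    "quantify": _stage_quantify,
    "diversity": _stage_diversity,
    "community": _stage_community,
    "enrich": _stage_enrich,
    "ancom": _stage_ancom,
    "network": _stage_network,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the enabled stages in dependency order.

    Writes every stage's outputs plus ``manifest.json`` (inputs,
    parameters, seed, versions, per-stage summaries) into the run
    directory, which is returned.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "bgcbiogeo",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in {"outdir", "synthetic", "stages"}
        },
        "synthetic": asdict(cfg.synthetic),
        "stages": {},
    }
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        started = time.time()
        summary = _STAGE_FUNCS[stage](cfg)
        manifest["stages"][stage] = {
            "summary": summary,
            "elapsed_s": round(time.time() - started, 2),
        }
        with open(cfg.outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, default=str)
    return cfg.outdir
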