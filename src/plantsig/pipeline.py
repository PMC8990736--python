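"""End-to-end orchestration of the signature-discovery pipeline.

``run_all`` executes the stages in order — identity cutoff → gene families →
core classification → PRB tagging → catalog screening → pool assembly →
abundance matrices → PCA + clustering → habitat association → KO enrichment →
plant-assay statistics (when assay data are present) — and returns a
machine-readable summary with per-stage counts and an echo of every
threshold used. Given the same inputs, configuration and seed the summary is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as psio
from .assay import assay_pca, assay_tests, scores_frame, zscore_standardize
from .enrichment import enrichment_summary, habitat_metric_test, ko_enrichment
from .pangenome import classify_core, cluster_gene_families, derive_identity_cutoff
from .pool import PrbThresholds, assemble_ppr, filter_prb, screen_gfobap
from .profiles import (build_abundance_matrix, habitat_association,
                       hierarchical_clusters, run_pca)
from .simulate import Cohort, CohortSimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and switches for one pipeline run."""

    simulate: bool = True
    sim: CohortSimConfig = field(default_factory=CohortSimConfig)
    input_dir: str | None = None  # used when simulate is False
    cutoff_override: float | None = None
    family_min_coverage_pct: float = 70.0
    core_fraction: float = 1.0
    prb: PrbThresholds = field(default_factory=PrbThresholds)
    gfobap_min_support: int = 2
    k: int = 3
    n_components: int | str = "auto"
    alpha: float = 0.05
    include_control: bool = True
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim = dict(raw["sim"])
            if "marker_identity_range" in sim:
                sim["marker_identity_range"] = tuple(sim["marker_identity_range"])
            if "assay_effects" in sim:
                sim["assay_effects"] = tuple(sim["assay_effects"])
            raw["sim"] = CohortSimConfig(**sim)
        if "prb" in raw and isinstance(raw["prb"], dict):
            raw["prb"] = PrbThresholds(**raw["prb"])
        return cls(**raw)


def load_cohort(input_dir) -> Cohort:
    """Read a cohort from the on-disk formats produced by ``write_cohort``."""
    d = Path(input_dir)
    matrices = {p.stem: psio.read_identity_matrix(p)
                for p in sorted((d / "markers").glob("*.tsv"))}
    assay_path = d / "assay.tsv"
    assay = psio.read_assay(assay_path) if assay_path.exists() else pd.DataFrame(
        columns=psio.ASSAY_COLUMNS)
    return Cohort(
        strains=psio.read_strains(d / "strains.tsv"),
        genes=psio.read_genes(d / "genes.tsv"),
        hits_self=psio.read_hits(d / "hits_self.b6"),
        hits_plant=psio.read_hits(d / "hits_plant.b6"),
        gfobap_features=psio.read_gfobap(d / "gfobap_features.tsv"),
        marker_matrices=matrices,
        assay=assay,
    )


def run_all(config: PipelineConfig | None = None,
            cohort: Cohort | None = None) -> dict:
    """Run every stage and return the summary bundle.

    A cohort may be passed in directly; otherwise it is simulated (with
    ``config.seed`` overriding the simulator seed) or loaded from
    ``config.input_dir``.
    """
    config = config or PipelineConfig()
    stages: dict = {}
    summary = {
        "seed": config.seed,
        "thresholds": {
            "cutoff_override": config.cutoff_override,
            "family_min_coverage_pct": config.family_min_coverage_pct,
            "core_fraction": config.core_fraction,
            "prb_max_evalue": config.prb.max_evalue,
            "prb_min_coverage_pct": config.prb.min_coverage_pct,
            "prb_min_identity_pct": config.prb.min_identity_pct,
            "gfobap_min_support": config.gfobap_min_support,
            "k": config.k,
            "n_components": config.n_components,
            "alpha": config.alpha,
            "include_control": config.include_control,
        },
        "stages": stages,
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        if config.simulate:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            cohort, _ = simulate_cohort(sim_cfg)
        else:
            if not config.input_dir:
                raise ValueError("simulate=False requires input_dir")
            cohort = load_cohort(config.input_dir)
    stages["inputs"] = {
        "n_strains": int(len(cohort.strains)),
        "n_genes": int(len(cohort.genes)),
        "n_hits_self": int(len(cohort.hits_self)),
        "n_hits_plant": int(len(cohort.hits_plant)),
        "n_markers": int(len(cohort.marker_matrices)),
    }

    def _fail(stage: str, err: Exception):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    try:
        report = derive_identity_cutoff(cohort.marker_matrices)
    except Exception as err:  # noqa: BLE001 - abort with stage name
        _fail("identity_cutoff", err)
    cutoff = (config.cutoff_override if config.cutoff_override is not None
              else report.chosen_cutoff)
    stages["identity_cutoff"] = {
        "mean_min": report.mean_min, "mean_max": report.mean_max,
        "chosen_cutoff": report.chosen_cutoff, "cutoff_used": cutoff,
    }

    try:
        assignment = cluster_gene_families(
            cohort.hits_self, cutoff, config.family_min_coverage_pct,
            cohort.genes)
        core = classify_core(assignment, cohort.strains, config.core_fraction)
    except Exception as err:  # noqa: BLE001
        _fail("gene_families", err)
    stages["gene_families"] = {
        "n_families": assignment.n_families(),
        "n_core_families": len(core),
    }

    try:
        prb = filter_prb(cohort.hits_plant, config.prb)
        gfobap = screen_gfobap(cohort.genes, cohort.gfobap_features,
                               config.gfobap_min_support)
        pool = assemble_ppr(prb, gfobap, assignment)
    except Exception as err:  # noqa: BLE001
        _fail("gene_pool", err)
    counts = pool.per_strain_count.reindex(
        cohort.strains["strain_id"], fill_value=0)
    stages["gene_pool"] = {
        "n_prb_genes": len(prb),
        "n_gfobap_genes": len(gfobap),
        "n_pool_genes": len(pool),
        "per_strain_mean": float(counts.mean()) if len(counts) else 0.0,
    }

    try:
        ko_matrix = build_abundance_matrix(
            pool, cohort.genes, "ko", strains=list(cohort.strains["strain_id"]))
        cog_matrix = build_abundance_matrix(
            pool, cohort.genes, "cog_category",
            strains=list(cohort.strains["strain_id"]))
        pca = run_pca(ko_matrix)
        clusters = hierarchical_clusters(pca, config.k, config.n_components)
    except Exception as err:  # noqa: BLE001
        _fail("profile_cluster", err)
    sizes = clusters.cluster_of.value_counts().sort_index()
    stages["profile_cluster"] = {
        "n_kos": len(ko_matrix.feature_ids),
        "n_cog_categories": len(cog_matrix.feature_ids),
        "cluster_sizes": {str(k): int(v) for k, v in sizes.items()},
    }

    if cohort.strains["habitat"].nunique() < 2 or clusters.k < 2:
        stages["association"] = {
            "skipped": True,
            "warning": "degenerate habitat x cluster table; association skipped",
        }
        logger.warning("habitat association skipped: degenerate table")
    else:
        try:
            assoc = habitat_association(clusters, cohort.strains)
        except Exception as err:  # noqa: BLE001
            _fail("association", err)
        stages["association"] = {
            "statistic": assoc.statistic, "df": assoc.df,
            "p_value": assoc.p_value, "low_expected": assoc.low_expected,
        }

    try:
        records = ko_enrichment(ko_matrix, clusters, config.alpha)
        if cohort.strains["habitat"].nunique() >= 2:
            H_len, p_len = habitat_metric_test(cohort.strains, "genome_length")
            H_ppr, p_ppr = habitat_metric_test(cohort.strains, "ppr_count", pool)
        else:
            H_len = p_len = H_ppr = p_ppr = float("nan")
    except Exception as err:  # noqa: BLE001
        _fail("enrichment", err)
    stages["enrichment"] = {
        "per_cluster": enrichment_summary(records),
        "genome_length_vs_habitat": {"H": H_len, "p": p_len},
        "ppr_count_vs_habitat": {"H": H_ppr, "p": p_ppr},
    }

    if len(cohort.assay):
        try:
            z = zscore_standardize(cohort.assay, config.include_control)
            tests = assay_tests(z)
            apca = assay_pca(cohort.assay, config.include_control)
        except Exception as err:  # noqa: BLE001
            _fail("assay", err)
        stages["assay"] = {
            "accumulated_z": {t: round(v, 6)
                              for t, v in z.accumulated.sort_index().items()},
            "tests": {k: {kk: round(vv, 6) for kk, vv in v.items()}
                      for k, v in tests.items()},
            "pc1_variance_pct": round(float(apca.variance_pct.iloc[0]), 6),
        }

    if outdir:
        _write_outputs(outdir, cohort, report, assignment, pool, ko_matrix,
                       cog_matrix, pca, clusters, records, stages, summary)
    return summary


def _write_outputs(outdir, cohort, report, assignment, pool, ko_matrix,
                   cog_matrix, pca, clusters, records, stages, summary):
    (outdir / "cutoff_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))
    assignment.frame.to_csv(outdir / "families.tsv", sep="\t", index=False)
    pool.frame.to_csv(outdir / "ppr_pool.tsv", sep="\t", index=False)
    (outdir / "pool_summary.json").write_text(json.dumps({
        "total": len(pool),
        "per_strain": {k: int(v) for k, v in pool.per_strain_count.items()},
    }, indent=2, sort_keys=True))
    ko_matrix.counts.to_csv(outdir / "abundance_ko.tsv", sep="\t")
    cog_matrix.counts.to_csv(outdir / "abundance_cog.tsv", sep="\t")
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pca.contributions_pct.to_csv(outdir / "pca_contributions.tsv", sep="\t")
    clusters.cluster_of.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t")
    records.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    if "association" in stages and not stages["association"].get("skipped"):
        (outdir / "association.json").write_text(
            json.dumps(stages["association"], indent=2, sort_keys=True))
    if len(cohort.assay):
        z = zscore_standardize(cohort.assay)
        z.z.to_csv(outdir / "assay_z.tsv", sep="\t", index=False)
        scores_frame(z).to_csv(outdir / "assay_scores.tsv", sep="\t", index=False)
        (outdir / "assay_tests.json").write_text(
            json.dumps(stages.get("assay", {}).get("tests", {}),
                       indent=2, sort_keys=True))
    (outdir / "summary.json").write_text(summary_json(summary))


def summary_json(summary: dict) -> str:
    """Canonical serialization of the run summary (stable across reruns)."""
    return json.dumps(summary, indent=2, sort_keys=True)


__all__ = ["PipelineConfig", "run_all", "load_cohort", "summary_json"]
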