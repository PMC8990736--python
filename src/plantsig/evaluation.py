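"""Monte-Carlo evaluation harnesses for the pipeline's statistical claims.

These run the package end to end on synthetic cohorts with planted truth
and measure recovery, calibration and power:

* planted-truth recovery on the full-scale default cohort (identity cutoff,
  core families, plant-related pool);
* cluster recovery — adjusted Rand index between the k=3 strain clusters
  and the true habitats (the small "other" group excluded from scoring);
* family-wise error of the KO enrichment over null cohorts, scored against
  a habitat-based partition (under the null the KO matrix carries no
  habitat signal, so habitats are an exchangeable, signal-independent
  grouping — testing against clusters fitted to the same matrix would be
  double dipping and no multiplicity correction could control it);
* detection power for planted signature KOs in a cohort where every
  habitat cluster has at least 20 strains (below that size the
  Kruskal-Wallis test is intrinsically underpowered at the planted fold);
* type-I calibration of the Kruskal-Wallis rejection rate.

Monte-Carlo repetitions use reduced gene inventories (the KO panel, strain
counts and planted-signal parameters stay at the defaults) and take family
assignments from annotated orthogroup labels; the homology-clustering route
is exercised separately by the recovery harness and its oracle tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .enrichment import ko_enrichment
from .pangenome import (assignment_from_orthogroups, classify_core,
                        cluster_gene_families, derive_identity_cutoff)
from .pool import assemble_ppr, filter_prb, screen_gfobap
from .profiles import (ClusterAssignment, build_abundance_matrix,
                       hierarchical_clusters, run_pca)
from .simulate import Cohort, CohortSimConfig, SyntheticTruth, null_cohort, simulate_cohort

#: Reduced gene inventory for Monte-Carlo repetitions.
MC_SLIM = dict(mean_genes=1600, sd_genes=120.0, n_core_families=200,
               n_accessory_families=1200, n_markers=3,
               prb_target_per_strain=40, prb_target_other=25)

#: Sensitivity harness: every non-empty habitat cluster has >= 20 strains.
SENSITIVITY_HABITATS = {"plant_associated": 25, "soil_rhizosphere": 29,
                        "marine_mangrove": 20, "other": 0}

#: Null-calibration harness: smallest inventory that still carries the full
#: 300-KO panel.
NULL_SLIM = dict(mean_genes=1000, sd_genes=80.0, n_core_families=50,
                 n_accessory_families=800, n_markers=2,
                 prb_target_per_strain=0, prb_target_other=0)

_HAB_GROUP = {"plant_associated": 1, "soil_rhizosphere": 2,
              "marine_mangrove": 3, "other": 3}


def spread_seed(base_seed: int, i: int) -> int:
    """Deterministic per-repetition seed below 2**31."""
    return (base_seed * 100_003 + 7919 * i + 1) % (2**31 - 1)


def ko_matrix_via_pipeline(cohort: Cohort, fast_families: bool = True):
    """Plant-related pool and KO abundance matrix through the package path."""
    if fast_families:
        asg = assignment_from_orthogroups(cohort.genes)
    else:
        cutoff = derive_identity_cutoff(cohort.marker_matrices).chosen_cutoff
        asg = cluster_gene_families(cohort.hits_self, cutoff, 70.0, cohort.genes)
    classify_core(asg, cohort.strains)
    pool = assemble_ppr(filter_prb(cohort.hits_plant),
                        screen_gfobap(cohort.genes, cohort.gfobap_features),
                        asg)
    matrix = build_abundance_matrix(pool, cohort.genes, "ko",
                                    strains=list(cohort.strains["strain_id"]))
    return pool, matrix


def recover_planted_truth(seed: int,
                          config: CohortSimConfig | None = None) -> dict:
    """Full-scale recovery run: cutoff, core families, pool vs planted truth."""
    config = config or CohortSimConfig()
    cohort, truth = simulate_cohort(dataclasses.replace(config, seed=seed))
    report = derive_identity_cutoff(cohort.marker_matrices)
    asg = cluster_gene_families(cohort.hits_self, report.chosen_cutoff, 70.0,
                                cohort.genes)
    core = classify_core(asg, cohort.strains)
    prb = filter_prb(cohort.hits_plant)
    gfobap = screen_gfobap(cohort.genes, cohort.gfobap_features)
    pool = assemble_ppr(prb, gfobap, asg)
    hab = cohort.strains.set_index("strain_id")["habitat"]
    prb_counts = pd.Series(0, index=hab.index, dtype=float)
    for s, _ in prb:
        prb_counts[s] += 1
    pa = prb_counts[hab == "plant_associated"]
    return {
        "chosen_cutoff": report.chosen_cutoff,
        "n_core": len(core),
        "core_exact": core == truth.core_family_ids,
        "pool_exact": pool.members == truth.ppr_true_genes,
        "n_pool": len(pool),
        "prb_mean_plant": float(pa.mean()) if len(pa) else float("nan"),
        "genes_per_strain_mean": float(cohort.strains["n_genes"].mean()),
        "n_strains": int(len(cohort.strains)),
    }


def cluster_recovery_aris(seeds: list[int]) -> list[float]:
    """ARI of k=3 clustering vs true habitat over planted cohorts."""
    aris = []
    for seed in seeds:
        cohort, truth = simulate_cohort(CohortSimConfig(seed=seed, **MC_SLIM))
        _, matrix = ko_matrix_via_pipeline(cohort)
        clusters = hierarchical_clusters(run_pca(matrix), 3)
        hab = pd.Series(truth.habitat_of)
        mask = hab != "other"
        aris.append(adjusted_rand_score(
            hab[mask], clusters.cluster_of.reindex(hab[mask].index)))
    return aris


def null_fwer(n_reps: int, base_seed: int) -> float:
    """Fraction of null cohorts with any KO at q < 0.05 (habitat grouping)."""
    hits = 0
    for i in range(n_reps):
        cohort, truth = null_cohort(
            CohortSimConfig(seed=spread_seed(base_seed, i), **NULL_SLIM))
        _, matrix = ko_matrix_via_pipeline(cohort)
        cl = pd.Series([_HAB_GROUP[truth.habitat_of[s]]
                        for s in matrix.strain_ids], index=matrix.counts.index)
        assignment = ClusterAssignment(cluster_of=cl, k=3, linkage_record=None)
        records = ko_enrichment(matrix, assignment)
        hits += bool((records["q_value"] < 0.05).any())
    return hits / n_reps


def signature_detection_rates(seeds: list[int]) -> list[float]:
    """Per-seed fraction of planted signature KOs at q < 0.05, in a cohort
    where every habitat cluster has >= 20 strains."""
    rates = []
    slim = dict(MC_SLIM, n_per_habitat=dict(SENSITIVITY_HABITATS),
                prb_target_per_strain=0, prb_target_other=0)
    for seed in seeds:
        cohort, truth = simulate_cohort(CohortSimConfig(seed=seed, **slim))
        _, matrix = ko_matrix_via_pipeline(cohort)
        clusters = hierarchical_clusters(run_pca(matrix), 3)
        records = ko_enrichment(matrix, clusters)
        q_by_ko = records.groupby("ko")["q_value"].first()
        detected = q_by_ko.reindex(sorted(truth.signature_ko_ids)) < 0.05
        rates.append(float(detected.mean()))
    return rates


def kw_null_rejection_rate(n_sims: int, seed: int, alpha: float = 0.05) -> float:
    """Type-I rate of the Kruskal-Wallis test on identically distributed
    continuous groups (3 x 30 observations)."""
    from .enrichment import kruskal_wallis
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_sims):
        groups = [rng.normal(size=30) for _ in range(3)]
        _, p = kruskal_wallis(groups)
        rej += p < alpha
    return rej / n_sims


__all__ = ["MC_SLIM", "NULL_SLIM", "SENSITIVITY_HABITATS", "spread_seed",
           "ko_matrix_via_pipeline", "recover_planted_truth",
           "cluster_recovery_aris", "null_fwer", "signature_detection_rates",
           "kw_null_rejection_rate"]
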