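"""Build the putative plant-related (PPR) gene pool for a cohort.

Derives the protein-identity cutoff from core-marker matrices, clusters
genes into families from homology hits, classifies the core genome, tags
plant-resembling bacterial (PRB) genes against the plant proteome
(E <= 1e-30, coverage >= 70%, identity >= 30%), screens annotations against
the plant-adaptation feature catalog, and pools everything minus the core.
"""

from plantsig import (CohortSimConfig, assemble_ppr, classify_core,
                      cluster_gene_families, derive_identity_cutoff,
                      filter_prb, screen_gfobap, simulate_cohort)

cohort, truth = simulate_cohort(CohortSimConfig(
    seed=7, mean_genes=1600, sd_genes=120.0, n_core_families=200,
    n_accessory_families=1200, n_markers=3,
    prb_target_per_strain=40, prb_target_other=25))

report = derive_identity_cutoff(cohort.marker_matrices)
print(f"marker identities: mean min {report.mean_min:.1f}%, "
      f"mean max {report.mean_max:.1f}% -> cutoff {report.chosen_cutoff:.0f}%")

families = cluster_gene_families(cohort.hits_self, report.chosen_cutoff,
                                 min_coverage_pct=70.0, genes=cohort.genes)
core = classify_core(families, cohort.strains)
print(f"{families.n_families()} gene families, {len(core)} core "
      f"(planted: {len(truth.core_family_ids)})")

prb = filter_prb(cohort.hits_plant)
flagged = screen_gfobap(cohort.genes, cohort.gfobap_features)
pool = assemble_ppr(prb, flagged, families)
print(f"PRB genes: {len(prb)}  catalog-flagged: {len(flagged)}  "
      f"pool after core subtraction: {len(pool)}")
print(f"per-strain pool sizes: mean {pool.per_strain_count.mean():.0f}, "
      f"min {pool.per_strain_count.min()}, max {pool.per_strain_count.max()}")
# Core families are shared by every strain and carry no habitat signal;
# the pool keeps only the genes that can differentiate the lifestyles.
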