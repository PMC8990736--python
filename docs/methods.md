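# Methods

## The problem and the model

`plantsig` addresses a comparative-genomics question: given a cohort of
related bacterial genomes isolated from different habitats, which gene
functions distinguish the plant-associated lifestyle? The approach treats
"plant-relatedness" of a gene as a union of evidence — direct homology to
host-plant proteins, or membership in a published catalog of bacterial
plant-adaptation features — and removes the core genome, which by
construction cannot discriminate habitats. Downstream statistics then
operate on per-strain functional profiles of this pool.

## Pipeline stages and their parameters

**Identity cutoff.** Each of the 92 universal bacterial marker genes
yields a square percent-identity matrix over the cohort. Off-diagonal
minima and maxima are averaged over markers; the chosen cutoff is the mean
minimum rounded *down* to the nearest multiple of 5. The published
workflow reports the derived means and an operative 70% threshold but not
the rounding rule; flooring to a 5% grid is this package's decision,
reproducing 70% whenever the mean minimum falls in [70, 75). The cutoff is
overridable (`cutoff_override`).

**Gene families.** Families are single-linkage connected components over
bacteria-vs-bacteria hits with identity ≥ cutoff and query coverage ≥ 70%
(both inclusive). This replaces a full pan-genome pipeline (CD-HIT/MCL
paralog splitting, synteny) with the simplest construction that preserves
what downstream stages consume: which families are present in every
strain. Family ids are the lexicographically smallest `(strain, gene)`
member, making the partition independent of input order. Core means
presence in 100% of strains by default (`core_fraction` relaxable; common
pan-genome tools default to 99%).

**PPR pool.** PRB tagging keeps a gene when *any* plant-proteome hit
passes E ≤ 1e-30, query coverage ≥ 70%, identity ≥ 30% — all comparisons
inclusive, coverage computed on the bacterial query (the protein being
classified). Catalog screening keeps features flagged plant-associated
with support from ≥ 2 statistical approaches, and matches genes by KO,
any Pfam/TIGRFAM id, orthogroup, or COG letter (OR semantics; the unit of
interest is the gene, not the annotation). Core subtraction is applied
last to the union; set subtraction makes the order immaterial.

**Profiles, PCA, clustering.** COG and KO count matrices are built over
the pool; KOs present in fewer than two strains are dropped (no
comparative signal). PCA centers and scales columns (correlation PCA, the
convention of the R toolchain this workflow mirrors), computed by SVD with
a deterministic sign convention (largest-|loading| entry positive). Ward
agglomeration (scipy, Ward.D2 convention) runs on the leading component
scores and is cut at k = 3, the observed cluster count; k is
configurable. Component retention: `n_components="auto"` keeps as many
components as clusters sought. A ≥ 80% cumulative-variance rule
(available as `"var80"`) was evaluated and rejected: with ~300
near-isotropic standardized KO columns and 74 strains, the bulk of the
spectrum is Marchenko-Pastur noise (bulk edge ≈ 5 vs signal eigenvalues
≈ 6), so a cumulative-variance rule retains ~44 components and cluster
recovery collapses (0.30 of seeds reach ARI ≥ 0.8, vs ~0.98 with the
k-component rule at the same planted signal). Clusters are renumbered by
decreasing size, ties by smallest member id, for platform-independent
output.

**Habitat association.** Pearson chi-square without continuity
correction; adjusted standardized residuals
(O − E)/√(E(1 − row/n)(1 − col/n)) localize the association. Expected
cells < 5 raise a warning, not an error — small habitat groups are a fact
of such cohorts.

**Enrichment.** The published workflow names the correction (Bonferroni
over KOs, q < 0.05) but not the test generating the per-KO p-values; this
package uses Kruskal-Wallis of per-strain copy numbers across clusters,
consistent with the nonparametric toolkit declared elsewhere in the same
workflow. One global test per KO; direction is assigned per cluster from
fold = cluster mean / overall mean (means over strains; the overall mean
includes the focal cluster). "Strong" (fold ≥ 2 or ≤ 0.5) is a label, not
a second significance gate. Bonferroni m = number of KOs surviving the
unique-strain filter, applied once across all KOs. KOs absent everywhere
are skipped with a log entry.

**Plant assay.** Z-scores use the sample (n−1) SD, pooled over all plants
of all treatments, controls included by default (both pooling choices are
flags; the published description does not fix them). Flower/fruit counts
are treated as continuous, as a Z-score treatment implies. The assay PCA
runs on treatment means of the standardized parameters with scaling off
(already on a common scale).

## The synthetic cohort

The generator emulates the *statistical* structure of the real cohort; no
sequences are simulated, only annotation tables and alignment statistics.
Defaults are the study-scale conditions: 25/29/14/6 strains across
plant/soil/marine/other habitats; per-strain gene counts from a truncated
normal (mean 6,407, SD 300); 992 single-copy core families (one gene per
strain each, making the planted core count exact); 92 marker matrices
with off-diagonal identities uniform on (72, 98)% so the derived cutoff is
70; Poisson KO copy numbers (base rate 2.0 per strain) for 300 KOs, of
which 40 are habitat signatures elevated 2.5-fold in a home habitat;
plant-proteome hits drawn to straddle every PRB threshold (E-values
log-uniform over [1e-40, 1e-20], identities uniform 25-35%, coverages
60-80%), with candidate counts set so the expected number of passing genes
per plant-associated strain is 307 (230 elsewhere); assay effects of
+1.0/+0.4/0.0 SD for plant/soil/marine treatments. Gene-count and
copy-number distributions (truncated normal, Poisson) are modeling
choices matching the reported first and second moments; published data
constrain nothing further.

Signature KOs are assigned home habitats round-robin across the three
major habitats (smallest habitat first), each elevated by the same fold.
Elevating only the plant habitat would leave soil and marine strains
statistically exchangeable — no clustering could separate them — so
habitat-resolved rates are required for a three-cluster structure to
exist at all. Within-family homology hits are emitted as a spanning chain
per family (sufficient for single-linkage and linear rather than
quadratic in family size), plus below-cutoff decoy pairs exercising the
thresholds.

What the generator does *not* emulate: phylogenetic autocorrelation
between strains, annotation errors and missingness, paralog inflation of
core families, compositional coupling between KOs, or overdispersed
(non-Poisson) copy numbers. Passing recovery tests therefore shows the
pipeline's logic and statistics are correct under a clean generative
model, not that real cohorts are this well behaved.

## Evaluation harnesses and problem sizes

`plantsig.evaluation` measures the package's statistical claims:

* **Planted-truth recovery** runs the homology-clustering route at full
  default scale (74 strains × ~6,400 genes) once: derived cutoff, exact
  core recovery, pool-vs-truth set algebra, PRB calibration.
* **Cluster recovery** (20 seeds) and **detection power** (30 seeds) use
  reduced gene inventories (~1,600 genes/strain, 200 core families) that
  leave the KO panel, strain counts and planted-signal parameters at the
  defaults — the KO abundance matrix, and hence the measured quantity, is
  unchanged by inventory size. Family assignments for these repetitions
  come from the annotated orthogroup labels
  (`assignment_from_orthogroups`), the fast path for cohorts with
  precomputed ortholog groups.
* **Detection power** is measured where the sensitivity claim applies: at
  the planted fold of 2.5 the Kruskal-Wallis test has adequate power only
  for home clusters of ≥ 20 strains (a 14-strain cluster's intrinsic
  power is ≈ 0.69), so the harness cohort uses 25/29/20/0 strains —
  every habitat cluster at or above that size.
* **Null calibration** (200 cohorts with no planted signal) scores the
  family-wise error of the enrichment against a habitat-based partition.
  Clustering the null KO matrix and then testing the same KOs across the
  fitted clusters is double dipping — measured FWER ≈ 0.45 — and no
  multiplicity correction controls it; against a partition independent of
  the tested matrix the Bonferroni guarantee holds (measured ≈ 0.04).
  This is also the practical caveat for real use: enrichment q-values are
  calibrated with respect to an externally defined grouping, and are
  exploratory when the grouping was fitted to the same matrix.
* **Kruskal-Wallis type-I rate** over 500 continuous null simulations
  (3 × 30 observations) checks the p-value calibration of the shared test.

## Numerical and degenerate-input conventions

All thresholds compare inclusively. Readers validate schemas and report
the offending line/key. Zero-variance features are dropped (logged)
before PCA scaling; an all-zero-variance matrix is an error. A
Kruskal-Wallis on identical observations degenerates to H = 0, p = 1. A
single-habitat cohort skips the association stage with a recorded
warning instead of failing the run. `run_all` is byte-identical across
reruns for fixed inputs, configuration and seed; every threshold used is
echoed in the summary.

## Known limitations

Single-linkage families chain easily at permissive cutoffs and carry no
paralog resolution; the 992-family core is exact only under the
generator's one-copy-per-strain assumption. Enrichment direction uses
means, so a single high-copy strain can tilt a cluster's fold. The
chi-square p-value is asymptotic and rough for small habitat groups (the
warning flags this). The assay statistics assume independent plants —
no plate, batch or repeated-measure structure.
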