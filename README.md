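# plantsig

Habitat-linked genomic signature discovery for bacterial cohorts.

Plant-beneficial bacteria (e.g. *Micromonospora* endophytes) are classically
selected by screening a handful of plant-growth-promotion traits, which turn
out to be poor predictors of who actually colonizes a plant. `plantsig`
implements the comparative-genomics alternative: pool every gene with any
plant-related evidence, strip away the core genome shared by all strains,
and ask which functional profiles separate strains by their isolation
habitat (plant tissue, soil/rhizosphere, marine/mangrove sediment, other).

The pipeline, stage by stage:

1. **Identity cutoff** — per-marker identity matrices of 92 universal core
   genes give per-marker off-diagonal minima/maxima; the mean minimum,
   floored to a multiple of 5, becomes the protein-clustering cutoff
   (70% for a typical congeneric cohort).
2. **Gene families / core genome** — single-linkage components over
   bacteria-vs-bacteria homology hits with identity ≥ cutoff and query
   coverage ≥ 70%; families present in every strain are the core.
3. **PPR pool** — "plant-resembling bacterial" (PRB) genes have a hit
   against the host-plant proteome with E ≤ 1e-30, coverage ≥ 70% and
   identity ≥ 30%; genes whose KO/Pfam/TIGRFAM/orthogroup annotations match
   a plant-adaptation catalog feature supported by ≥ 2 statistical
   approaches are added; core-family members are subtracted.
4. **Profiles and clusters** — per-strain COG-category and KO count
   matrices over the pool; standardized PCA; Ward agglomeration in
   component space cut at k = 3; Pearson chi-square of habitat × cluster
   with adjusted standardized residuals.
5. **Enrichment** — per KO, Kruskal-Wallis of copy numbers across
   clusters; Bonferroni q = min(1, m·p) over all m KOs; per-(KO, cluster)
   fold = cluster mean / overall mean, with |fold| ≥ 2 or ≤ 0.5 flagged as
   the conventional two-fold highlight.
6. **Plant assay** — Z-score standardization of four growth parameters
   (z = (x − x̄)/s, pooled over all plants), accumulated per-treatment
   scores, per-parameter Kruskal-Wallis, and a PCA of treatments against
   parameters.

A fully seeded synthetic-cohort generator (`plantsig.simulate`) emulates
the statistical structure of a 74-strain cohort — planted core families,
habitat-signature KOs, hit scores straddling every PRB threshold — so that
each stage can be scored against known truth.

## Worked example

```bash
python examples/02_build_gene_pool.py
```

prints (reduced cohort, seed 7):

```
marker identities: mean min 72.0%, mean max 98.0% -> cutoff 70%
1400 gene families, 200 core (planted: 200)
PRB genes: 2252  catalog-flagged: 48050  pool after core subtraction: 49008
per-strain pool sizes: mean 662, min 589, max 745
```

The derived 70% cutoff reproduces the planted marker calibration; all 200
planted core families are recovered exactly and removed from the pool, and
each strain contributes a few hundred candidate plant-related genes. The
other examples cover simulation (`01`), strain clustering and the habitat
chi-square (`03`), KO enrichment (`04`) and the plant assay (`05`).

There is also a thin CLI mirroring the stages:

```bash
plantsig simulate --seed 3 --outdir cohort/
plantsig run-all --seed 3 --outdir results/
```

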