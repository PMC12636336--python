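# Methods

`funnelqtl` implements the statistical pipeline for QTL mapping in an
8-founder haploid yeast multiparent population, together with a
simulator that generates data with the statistical structure the
analysis assumes. This note documents the models, the parameters that
matter, the numerical choices, and what the simulator does and does
not emulate.

## The mapping population and its simulator

The study design is a funnel cross: eight genetically diverse haploid
founders are combined through three rounds of crossing so that every
final strain is a recombinant mosaic of all eight founder haplotypes,
recorded as a founder-of-origin label (1–8) at every variant position.
Because the strains are haploid, no inbreeding is needed and there is
no dominance.

The simulator (`simcross`) builds this structure explicitly:

* **Founder panel.** Variant positions are Poisson along each
  chromosome (default density 1/44 bp, the density of the real founder
  panel). Each variant is biallelic; the number of founders carrying
  the minor allele is drawn from a configurable spectrum, by default
  uniform on 1–4 carriers, so both rare (founder-private) and common
  variants exist. Introgressed blocks — founder-private divergent
  segments like the non-*cerevisiae* introgressions segregating in the
  real panel — are modelled as windows where all alleles are private
  to one founder, at elevated variant density.
* **Meiosis.** Crossover counts per chromosome per meiosis are
  Poisson(rate × length) with uniform positions and no interference;
  the default per-meiosis rate of 3×10⁻⁶ /bp yields ~0.09 crossovers
  per 10 kb on a final chromosome after the three rounds of meiosis,
  matching the observed aggregate density. One chromatid is
  transmitted and carries every crossover of its meiosis. Crossovers
  that join identical founder labels are invisible in the haplotype
  matrix but are retained in the breakpoint bookkeeping; the expected
  visible density is rate × (1 + (r−1)·7/8) for r rounds, since a
  round-1 crossover always joins two distinct founders while a later
  crossover joins two independent uniformly-labelled products (which
  coincide with probability 1/8). This closed form is verified by the
  test suite.
* **Funnel.** Round 1 mates the fixed founder pairs (1×2, 3×4, 5×6,
  7×8); rounds 2 and 3 mate uniformly sampled products of the previous
  round, mimicking pooled reciprocal crossing. Pool bookkeeping is not
  modelled: each strain's pedigree is drawn independently, which is
  the large-pool limit.
* **Traits.** A trait architecture is a set of causal loci (per-founder
  allele classes with per-class additive effects), optional epistatic
  terms (effect tables over allele-class combinations, which express
  masking and sign-inversion patterns), strain-level biological noise
  and replicate-level measurement noise. When `target_h2` is set the
  strain noise is solved so that the realized additive fraction of
  strain-level variance equals the target on the simulated population.
* **Plates.** Phenotyping is emulated as 8×12-well plates with 88 test
  wells, the 8 founder control patches per plate at fixed interior
  positions, duplicate measurements (each replicate a batch), and
  multiplicative plate, batch, and edge×condition artifacts drawn
  log-normally around a baseline patch area of 5000 px. True
  (pre-artifact) values are retained for validation.

What the simulator does **not** emulate: sequencing and haplotype
inference error (labels are exact), aneuploidy and viability
selection, crossover interference, spatial gradients within plates
beyond the edge rings, and non-Gaussian measurement error. Passing
tests therefore validate the statistics given correctly inferred
haplotypes, not robustness to genotyping error.

## Normalization (`phenonorm`)

Raw patch areas pass through four steps, in this order, and the order
is recorded in the output metadata:

1. **Masking** — areas ≤ 2000 px (approximately the pin deposition
   footprint) become missing; the boundary is inclusive.
2. **Plate** — a multiplicative factor per plate, the geometric mean
   over that plate's founder controls of (control value /
   across-plate geometric mean of the same founder control).
   Log-scale averaging is robust to founder-specific growth
   differences. A plate with no usable controls gets factor 1 with a
   warning.
3. **Batch** — each (batch, condition, timepoint) group is scaled so
   its median equals the global median for that condition+timepoint.
4. **Edge** — the model value of an edge well is E(edge, timepoint) ×
   C(condition, timepoint); both factor sets are estimated per
   timepoint by OLS on log values of edge wells relative to their
   plate's interior mean-log, with the first condition as reference
   (C=1). Corners are assigned to the top/bottom edges — the model
   needs a deterministic convention and the choice is symmetric.

Final phenotypes are the mean of non-missing normalized replicates per
strain/condition/timepoint. The plate and batch steps are pure
scalings, so within-plate strain ranking is preserved. On simulated
data with default artifact magnitudes the composed pipeline removes
>99% of artifact-attributable log-variance.

## Heritability (`heritability`)

**Broad sense.** H² = 1 − σ²ₑ/σ²ₛ, with σ²ₛ the variance of observed
strain means and σ²ₑ the sampling variance of those means: the REML
residual variance of a one-way strain-random-intercept model divided
by the harmonic-mean replicate count (the harmonic mean generalizes
the duplicate design cleanly to unbalanced replication). H² is
reported unclipped, with a warning when ≤ 0.

**Narrow sense.** Founder labels are converted back to biallelic
calls at the scaffold markers via the founder allele table, recoded so
the major allele is 1, mean-imputed where missing, column-centered by
allele frequency, and assembled into K = ZZᵀ / Σp(1−p) — the haploid
analogue of the VanRaden kinship (the diploid 2Σp(1−p) scaling would
cancel in h² = Va/(Va+Ve) anyway). REML for y = μ + g + e,
g ~ (0, K·Va), maximizes the profiled restricted likelihood over the
variance ratio on the spectrum of K; when the marker count m is below
the strain count the eigendecomposition is done in marker space
(O(m³) + O(nm²)) with the zero-eigenvalue complement carried in sum
form. The optimizer is bounded Brent on log(Va/Ve) ∈ [−12, 12] with an
explicit boundary check at h²≈0; a dense-algebra grid search over h²
(step 0.01) serves as an independent cross-check in the tests. The
standard error is the SD of h² over bootstrap resamples of strains
(rows of Z and y resampled together; the marker-space decomposition
makes each replicate cheap).

## LOD scans and thresholds (`linkscan`)

At each marker the null model fits one mean and the QTL model a
separate mean per observed founder haplotype;
LOD = (n/2)·log₁₀(RSS₀/RSS₁). Strains missing the label or the
phenotype are dropped for that marker only and RSS₀ is recomputed on
the retained subset, so the comparison stays nested and n is
per-marker. Markers with a single observed haplotype score 0 and are
flagged. The scan is vectorized over marker blocks as eight
mask-matrix products, which also makes the permutation loop cheap.
Ties in "max LOD" resolve to the lowest (chromosome, position) because
markers are stored sorted.

**FWER.** The genome-wide, multi-phenotype threshold permutes which
strain's joint phenotype vector accompanies each haplotype row
(conditions stay linked), rescans all markers × phenotypes, records
the global max LOD, and takes the 95th percentile of (default) 1000
maxima.

**Pairwise interactions.** For a marker pair, the additive model fits
both haplotype main effects jointly by least squares and the full
model fits a mean per observed haplotype combination; with Gaussian
profile likelihoods LOD_i = (n/2)·log₁₀(RSS_add/RSS_full). Both RSS
are computed from 16×16 contingency-table normal equations, so the
all-pairs scan costs O(n) per pair. Candidate pairs default to
inter-chromosomal (plus intra-chromosomal pairs beyond a configurable
distance), because linkage inflates short-range interaction
statistics. The 1% FDR threshold uses one fresh permutation of the
additive-model residuals per pair as the null and takes the smallest
τ with (#null ≥ τ)/(#observed ≥ τ) ≤ level; +∞ (with a warning) when
nothing qualifies.

## Additive models and fine-mapping (`qtlmodel`)

Forward selection iterates: scan the current residuals over the
scaffold markers; keep the top marker per chromosome with LOD ≥ 9 (a
conservative round-up of the 5% FWER threshold); refit the joint OLS
of the phenotype on haplotype factors at all selected markers; stop
when no marker passes or the nested ANOVA against the previous
iteration's fit exceeds p = 0.001 (the last additions are then
discarded). Each factor uses the most frequent haplotype as reference;
strains with a missing label at any selected marker are dropped from
the refit; collinearity is absorbed by minimum-norm least squares with
rank-based ANOVA degrees of freedom and a warning.

Fine-mapping removes one model marker at a time, adds its fitted
effect contribution back onto the model residuals, rescans that
chromosome over the **full** marker set, and reports the peak, the
2-LOD interval (the positional span of all markers within 2 LOD of the
peak — a non-contiguous super-threshold set raises a flag, as does a
peak at a chromosome end), and 1 − RSS₁/RSS₀ at the peak on the
adjusted phenotype. Candidate genes are those whose strand-aware
window (ORF −1 kb upstream, +0.5 kb downstream) intersects the closed
interval. Gene lists of QTL with intervals <100 kb can be refined by
counting gene occurrences across the corresponding 24 h/48 h interval
sets and keeping the (co-)highest.

## Architecture statistics (`archstats`)

* **Cross-validated variance.** 10-fold CV; per fold the model is
  rebuilt on the training strains only and evaluated as
  1 − RSS_test/TSS_test about the test mean. Test strains with a
  haplotype unseen in training are dropped and counted. The per-k
  curve refits the k strongest training markers (drop-one type-II
  ANOVA ranking) and evaluates on the test fold.
* **Interaction extension.** Per fold, each model-QTL pair's
  single-interaction augmentation (observed-cell indicator block) is
  ANOVA-ranked against the additive base; interactions are added
  strongest-first until the sequential nested ANOVA p ≥ 0.001.
* **Multimodality.** The 8 haplotype effects at a QTL (haplotypes
  with fewer than `min_n` strains set to missing; `min_n` defaults to
  50 and should scale with population size, ~0.5%) are binarized by
  two-means clustering. In one dimension the optimal 2-means partition
  is an interval of the sorted values, so the clustering scans all
  sorted splits and is exactly optimal and deterministic (ties to the
  smallest split). Over 100 random 90:10 splits, full (8-level),
  binary, and null (QTL omitted) models — all keeping the other QTL at
  full encoding — are fit on train and the additional test variance
  versus null is recorded for full and binary. The one-sided test of
  full > binary is a t-test over splits, paired by default because
  both quantities share each split's test set (an unpaired variant is
  available); Holm correction is applied across all QTL pooled by the
  caller.
* **Pleiotropy.** Condition-wise single-gene lists are resampled
  uniformly without replacement from the gene universe (universe size
  is a required argument, not a default); the null statistic is the
  max number of conditions sharing a gene; the 95% quantile is the
  smallest count whose cumulative null probability reaches 0.95, and
  genes shared by more conditions are significant.
* **Effect-profile PCA.** Rows (conditions) standardized to zero
  mean/unit variance; component fractions are squared singular values
  of the standardized matrix over their sum. A constant row is an
  error naming the condition.

## Stratification (`strata`)

Subgroups are defined by haplotype at a master locus; strains whose
two flanking-marker labels disagree (or are missing) carry a crossover
across the locus, making the defining haplotype ambiguous, and are
excluded and counted. The discretization of a master locus into
classes is user-supplied, since in practice it comes from validated
causal alleles, not from the data. Subgroup scans use a per-subgroup
permutation threshold (99th percentile of 1000 single-phenotype
maxima). The global-versus-subgroup comparison draws, per split,
90:10 partitions within each subgroup, fits subgroup models, a
mean-only null, and a global model on the pooled training strains, and
evaluates all on each subgroup's test strains as residual variance
about the prediction; percent changes are relative to the null. The
four-way interaction test compares the full factorial cell-means model
of four loci (master discretized to two classes) against an additive
master effect plus the full three-way factorial of the other loci,
with rank-based F degrees of freedom.

## Problem sizes and defaults

The package's routine genome is 4 chromosomes × 250 kb at 1 variant /
44 bp (~22k variants, ~500 scaffold markers at 2 kb spacing) — the
same statistical structure as the full 16-chromosome, 12 Mb genome at
desk speed; the full-scale genome spec is available as a constant.
Validation experiments use populations of 1500–5000 strains, 1000
permutation maxima for FWER thresholds, 100 random splits for the
multimodality and locus-variance procedures, and 10 000 permutations
for the pleiotropy test, matching the analysis defaults.

## Known limitations

* The additive-model count for a trait depends on forward-selection
  tie-breaking and the exact stopping sequence; only the recovery of
  planted loci, not the exact model size, is asserted.
* The 2-LOD interval is reported as a span; for very strong QTL its
  nominal coverage is approximate.
* The pairwise FDR null uses one permutation per pair, as in the
  procedure it implements; its threshold is therefore itself a random
  variable with permutation noise.
* REML variance components are constrained non-negative by the
  log-ratio parameterization; estimates at the h²=0 boundary have
  non-standard bootstrap distributions.
* Subgroup comparisons refit forward selection per split, which is
  honest but means small subgroups can yield empty models; those
  splits fall back to the null model.
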