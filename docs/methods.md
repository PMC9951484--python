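# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want to know.

## Synthetic data generator

The generator emulates a prenatal-stress fetal-brain study design: a
labeled single-cell reference of the embryonic brain, a small two-batch
bulk RNA-seq cohort of whole-brain samples from both sexes, and an
ISH-energy-like voxel volume.

**Cell types and composition.**  16 cell classes; the default composition
is dominated by neurons (53.94%), neuroblasts (24.23%) and glioblasts
(13.75%), with radial glia at 2.1% and the remaining twelve classes
sharing the rest — the composition of the E15.5 mouse brain at the peak of
neurogenesis.  Each class is split into two subclasses that share a
profile; the subclass level exists to exercise the finer label granularity
of downstream code, not to model real subclass biology.

**Expression profiles.**  All types share a heavy-tailed log-normal
baseline (σ = 1.2 on the natural log, a realistic spread of relative
expression); a `marker_frac = 0.3` fraction of genes is assigned one home
type each (round-robin, then shuffled) and elevated `marker_fold = 8`-fold
there.  Profiles are column-normalized to relative expression.

**Counts.**  Negative binomial throughout with the mean/dispersion
parameterization `var = μ + μ²/dispersion`.  `nb_dispersion = 20`
(biological CV ≈ 0.22) is a typical dispersion for bulk RNA-seq of inbred
mouse tissue; single cells use a depth of 5,000 ± 30% counts, bulk samples
1e6 ± 10% (a scaled-down library that preserves the signal-to-noise regime
of deep sequencing for all but the faintest genes).

**Cohort.**  9 control vs 7 stressed samples, two batches, both sexes
(controls 5M/4F, stressed 3M/4F, generalized by alternating assignment).
Sex and batch act as gene-wise log-normal multipliers (sd 0.1) that are
independent of condition — real nuisance signal for the DE stage's
covariates to remove.  Litter structure is recorded in no way and not
modeled.

**Planted condition effects.**  Differential expression is planted
cell-type-specifically: a gene's fold change multiplies only the
expression contributed by its home types, mimicking cell-type-restricted
regulation.  The default blocks plant |log2FC| = 0.5 (mild effects,
as condition contrasts in whole tissue typically are): up-regulation
through radial glia, down-regulation through neurons, with block sizes
scaled to the gene universe (25 up / 35 down at 2000 genes, keeping more
down- than up-regulated genes).  A consequence worth knowing: effects
planted through a minority type are strongly attenuated in the bulk
mixture — a +1 log2FC through radial glia (2.1%) yields a bulk fold change
of only ~1.15 — so at the default effect sizes the bulk test finds few
individually significant genes, and the planted sets are recovered by the
enrichment stage instead.  `global_effect = True` plants classic all-type
fold changes for power checks.  A composition shift (+0.03 neuroblast,
−0.03 neuron under stress) is planted in the mixing fractions, which are
renormalized and recorded in the ground truth.

**Volume.**  A 12×10×8 grid partitioned into contiguous x-slabs, one per
region (eight developing-brain region names by default); z runs lateral →
medial so index 0 is the lateral-most sagittal plane.  Every panel gene
has one home region with `ish_fold = 10`-fold elevated mean energy over a
background of 1.0; energies are gamma-distributed (shape 5, CV ≈ 0.45;
shape 0 disables noise).  Planted up-/down-DE genes are homed to the
cortical plate / midbrain respectively so the spatial stage sees the same
planted structure as the rest of the pipeline.  No registration to real
atlas coordinates is attempted.

**Determinism.**  Every generator stage draws from its own
`SeedSequence([seed, stage])` substream; identical `(seed, config)` gives
bit-identical outputs, and regenerating one artifact never perturbs
another.

What passing tests on this generator do *not* show: real data have
correlated genes, zero inflation, ambient RNA, doublets, litter effects
and imperfect labels; none of these are modeled.  Recovery rates here are
upper bounds on real-data performance.

## Differential expression

A deliberately transparent stand-in for a negative-binomial DE fit: counts
are normalized with median-of-ratios size factors (the median over genes
with nonzero counts in all samples of the ratio to the gene's geometric
mean), log2-transformed with pseudocount 1, and fitted per gene by OLS
with design `intercept + sex + batch + condition`.  The condition
coefficient is the log2 fold change; its two-sided t-test p-value is
BH-adjusted over all tested genes.  Choices:

* **Variance moderation (default on).**  With 16 samples the per-gene
  residual variance has ~12 degrees of freedom and is the dominant source
  of error; the standard empirical-Bayes squeeze (inverse-gamma prior
  fitted to the observed variances by matching log-variance moments;
  posterior variance a prior/data compromise; t-test df increased by the
  prior df) stabilizes it.  Null calibration is unchanged (type-I error
  0.050 on null simulations) while recovery of planted log2FC = 1 genes
  rises from ~0.89 to ~1.0.
* **Expression filter.**  Genes with mean normalized count < 1 are not
  tested and are excluded from the BH family; the filter is configurable
  and recorded (`n_filtered`, set = "filtered").
* **Boundary rule.**  Significance is the strict `padj < α`; a gene at
  exactly α is background.  Background = tested, not significant — the
  "unchanged" comparison set for enrichment.
* **Zero variance.**  A gene constant in the (normalized, log) response
  gets p = 1, log2FC = 0.  Note that a raw-constant gene under unequal
  size factors is genuinely non-constant after normalization and is tested
  normally.
* **Scale invariance.**  Scaling one sample's counts by c rescales all
  normalized counts by the common factor c^(1/n), which the intercept
  absorbs; log2FC is invariant up to pseudocount effects at low counts
  (≤1e-3 for well-expressed genes).
* **Sex-stratified reruns** use `fit(subset="sex=M")`; a covariate left
  with one level after subsetting is dropped from the design (logged).
  Confounded designs (e.g. batch ≡ condition) are rejected with the
  collinear columns named.

No dispersion shrinkage on the mean-variance relation, no outlier
handling, no batch-correction of the values themselves (batch is a
covariate only).

## PEM and cell-type enrichment

Type profiles are the per-type means of depth-normalized cells (counts per
10k by default — an off-switch exists because raw-count averaging weights
deep cells more; types with < 3 cells are dropped with a warning).  A
pseudocount (default 1e-3, recorded on the result) is added to every entry
before the type totals `S` and the observed/expected ratio are formed, so
all PEM values are finite; pseudocount 0 is admissible when the matrix has
no zeros.  The construction satisfies, by algebra, the conservation
identity `Σ_i 10^PEM[g,i] · S_i / Σ S = 1` per gene, which the tests
verify to 1e-9 on random matrices.

The K-S stage compares DEG vs background PEM values per type
(`scipy.stats.ks_2samp`; asymptotic p-values by default, exact available).
The test direction is two-sided by default with the shift sign (median
DEG − median background) reported separately; `alternative="greater"`
tests specifically for enrichment toward higher PEM and is what the
planted-signal recovery analyses use.  BH is applied across the cell types
of one call — class and subclass levels are separate families.  The
enrichment score is `−log10(padj)`.

Note a structural effect of marker-based signal: genes up-regulated
through type A are A-markers, so their PEM in every *other* type sits
slightly below the background distribution; a two-sided test therefore
shows weak "significance" in unrelated types, while the one-sided
(greater) test correctly stays quiet there.

## Deconvolution

The signature takes the top-k genes by PEM per type (default k = 50; the
union is deduplicated), with values on a counts-per-million scale computed
against each type's full-universe total.  Bulk samples are CPM-scaled with
their full library and restricted to signature genes; mixtures are linear
in linear space, so no log transform is applied.  The fit is non-negative
least squares per sample with **inverse-mean row weights** (default):
RNA-seq noise is approximately multiplicative with constant CV, so its
variance grows with the squared mean, and 1/mean weights are the matching
weighted-least-squares choice; without them a few very high-expression
genes dominate the near-collinear signature columns and the fraction
estimates become noisy (on default simulations the weighting cuts the
fraction MAE from 0.019 to 0.012 and lifts detection of a +0.03 neuroblast
shift from 40% to 100% of seeds).  `weighting="none"` restores the plain
fit.  Coefficients are renormalized to sum to one; the residual norm is
kept per sample.  Group comparison is an unpaired Welch t-test per type,
uncorrected (the per-type bar-plot convention); identical groups return
t = 0, p = 1.

Known limitation: composition estimates and cell-type-specific expression
changes are confounded.  When a condition down-regulates neuron-derived
transcripts, the neuron markers genuinely carry less signal and the
estimated neuron fraction drops by more than the true composition shift.
This is inherent to signature deconvolution, not specific to this
implementation; fraction differences between groups should be read as
composition-weighted expression shifts.

## Brain-region mapping

A module's spatial score is the voxel-wise sum of the energies of the
module genes available in the volume's panel; absent genes are dropped and
counted (`n_genes_available`), never imputed — since absent genes would
contribute no energy either way, this differs from zero-filling only in
bookkeeping.  No per-gene scaling is applied before summation (raw
energies are summed); region summaries report voxel count, sum and mean,
ranked by mean, and the two-module contrast is
`log2((mean_up + ε)/(mean_down + ε))` with ε = 1e-6.  Sections are plain
array slices along the stated axis, no interpolation.  Any display
transform (log-scaling, thresholding) is left to the user.

## Pipeline and I/O

Stages run in a fixed dependency order; every output is a plain-text file
(TSV / MTX with name sidecars / GMT / long-format volume TSV) whose
writer–reader pairs round-trip exactly.  The manifest records the package
version, a hash of the semantically meaningful configuration (output paths
and log level excluded), sha256 checksums of every output, timestamps and
captured warnings, and is written even when a stage fails (with the
failing stage and message).  Genes are matched across bulk, reference and
volume by exact case-sensitive symbol; every stochastic stage logs its
seed.

## Problem sizes in tests and the acceptance script

The checks run on scaled-down instances chosen to keep the statistical
question intact: 500–1000 genes, 15–50 cells per type, 16-sample cohorts,
20 Monte-Carlo seeds for recovery rates (binomial SE ≈ 0.07 at p = 0.9),
100 seeds for null calibration of the K-S stage, and 500 random instances
for the exact oracle comparisons.  These sizes were fixed as the smallest
at which the Monte-Carlo error is comfortably below the margins being
tested.
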