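# Methods

## Data representation

The canonical input is a long table of per-barcode counts: one record
per (technical replicate, barcode) with the assigned oligo and its DNA
and RNA counts.  Modeling uses a wide frame with one row per variant (or
element) and one column per *barcode slot* per replicate.  Columns are
grouped contiguously by replicate (the blocking vector).  In variant
mode each replicate block holds the reference slots followed by the
alternative slots; both sides share one slot width — the maximum barcode
multiplicity over all mapped oligos — and sequences with fewer barcodes
are padded with *missing* slots.  Missing slots carry zero weight in
every downstream computation and are excluded from the effective block
size; counts are never imputed.  Within an oligo, barcodes fill slots in
lexicographic order, so a barcode occupies the same slot position in
every replicate and frame construction is deterministic under record
permutations.

## Preprocessing

Four steps, each purely subtractive (defaults in parentheses):

1. **Minimum counts** (1): keep barcodes with DNA and RNA counts at or
   above the threshold in *every* replicate; a barcode absent from a
   replicate fails.
2. **Minimum barcodes** (10): drop oligos with fewer surviving barcodes.
3. **RNA outlier removal** (3 SD): per oligo and per replicate, compute
   the mean and sample (n−1) SD of raw RNA counts over barcodes; a
   barcode deviating by more than 3 SD in *any* replicate is removed
   from *all* replicates.  Zero-SD groups remove nothing.  Whether to
   pool replicates here is genuinely open; per-replicate scoring was
   chosen because replicate depths differ, and it is the stricter test.
   On clean simulated data the removed fraction is the union over
   replicates of the (right-skewed) NB 3-SD tail — about 2% with six
   replicates, not the Gaussian 0.3%.
4. **Downsampling** (95th percentile): cap barcode multiplicity at the
   given percentile (linear interpolation, floored to an integer) of the
   per-oligo multiplicity distribution; oligos above the cap keep a
   uniformly random cap-sized subset, deterministic given the seed.

## Normalization and log-ratios

Library sizes are computed per replicate block: the total DNA (resp.
RNA) count over all rows and all of the block's columns.  The activity
of a cell is

    logratio = log2((rna + c) / L_RNA · 10⁶) − log2((dna + c) / L_DNA · 10⁶)

with pseudocount c = 1.  Depth scaling cancels within a replicate
exactly when c = 0 and asymptotically for counts ≫ c.  The pseudocount
biases log-ratios of very low counts toward zero; the default filters
(counts ≥ 1, means ≥ 20 in the simulator) keep this bias small relative
to sampling noise.

## Precision weights

A single mean–variance trend is estimated across all rows: each row is
fitted by OLS on its design, and a LOWESS curve (span 0.5, statsmodels
implementation) of the quarter-root residual variance `s^{1/2}` against
the row's mean log2 DNA abundance is interpolated, clamped at the fitted
range; the weight of a cell is the interpolated trend value to the power
−4, and exactly zero for missing cells.

Where to evaluate the trend for each cell was a genuinely open choice.
Evaluating at the cell's **own observed** DNA abundance is tempting —
high-count barcodes should get more weight — but it ties the weight to
the cell's own sampling noise: a randomly high DNA draw simultaneously
raises the weight and lowers the log-ratio, so weights and residuals
become negatively correlated.  In testing, this correlation gave the
√w-scaled residuals a systematic nonzero block sum that perfectly mimics
a replicate random effect: the consensus-correlation REML was driven to
ρ ≈ 0.99 even on data simulated with fully independent columns.  This
is the same reason the voom procedure evaluates its trend at fitted
rather than observed log-counts.  The implementation therefore
interpolates at the slot's **leave-own-replicate-out** mean DNA
abundance (falling back to the row mean when a slot is observed in fewer
than two replicates): barcodes with genuinely high representation still
receive high weights, but a cell's weight is independent of its own
noise.

## Consensus within-replicate correlation

Barcodes measured in the same technical replicate share replicate-level
effects, modeled as a compound-symmetric correlation ρ within each
block, independent across blocks, shared by all rows.  Per row, ρ is
estimated by restricted maximum likelihood on the weighted data; the
restricted log-likelihood is profiled over a grid of 81 ρ values (from
just above −1/(m−1), m the largest effective block, to 0.99) with a
parabolic refinement around each row's optimum.  Per-row estimates are
pooled by a 15%-trimmed mean on the atanh scale and transformed back.
Rows whose blocks all contain fewer than two usable cells carry no
information about ρ and are excluded; if no row is informative (e.g.
aggregated element mode, one column per replicate) the correlation is
unidentifiable and the caller is directed to the independent-columns
fit.

The estimator was validated against the R reference implementation of
the same consensus-correlation idea (limma `duplicateCorrelation`): on a
2000-row dataset with true ρ = 0.5 and 12 observations per row both
return 0.4047 (agreement to 4 decimals).  The shared downward shrinkage
at small per-row sample sizes is a property of the estimator, not a
defect; at the barcode scale (hundreds of observations per row) the
estimate is accurate, e.g. within ±0.05 of zero on independent data.

## Row-wise weighted GLS

All computations exploit the closed-form inverse of an m×m
compound-symmetric correlation block, Σ_b⁻¹ = aI + bJ with
a = 1/(1−ρ) and b = −ρ/((1−ρ)(1+(m−1)ρ)), where m is the row's count of
non-missing cells in that block.  Any bilinear form u'V⁻¹v with
V = W^{−1/2} Σ W^{−1/2} then reduces to weighted elementwise sums plus
per-block sums of √w-scaled vectors, so the normal equations for all
rows are assembled by two einsum contractions, with the data-dependent
cross-products precomputed once and reused for the whole REML grid.
This is algebraically identical to whitening with a Cholesky factor of
V but runs vectorised across rows without factorising any matrix larger
than the design.  Rows whose non-missing columns leave the design
rank-deficient (determinant below 1e−10 of the diagonal product) or with
no residual degrees of freedom are flagged, reported as NaN, and
excluded from moderation and multiple-testing.

Aggregate mode sums raw counts over barcode slots per (replicate,
allele) before normalization — reproducing the classical aggregated
analysis — and then runs the identical chain on the collapsed frame.

## Empirical Bayes moderation and tests

Residual variances are shrunk assuming s_g² | σ_g² is scaled chi-square
with df_g and σ_g² has a scaled inverse-chi-square prior (d₀, s₀²).  The
prior is estimated by moment matching on
e_g = log s_g² − ψ(df_g/2) + log(df_g/2): the mean of e gives s₀², its
excess variance over the trigamma term gives d₀ through the trigamma
inverse (Newton iteration).  Non-positive excess variance means the
observed spread is consistent with pure chi-square noise; then d₀ = ∞
and every posterior variance equals s₀².  Note that in this degenerate
branch s₀² equals the common s² only up to the finite-df factor
exp(log(df/2) − ψ(df/2)) ≈ 1 + 1/df, a property of the unbiased-log
moment estimator.  Moderated t-statistics t = β/(√s²_post · su) are
referred to a t-distribution on df_g + d₀ degrees of freedom (normal
when d₀ = ∞), two-sided, with Benjamini–Hochberg adjustment across
tested rows.  With fewer than two usable rows, moderation is skipped
with a warning.

## Threshold tests against negative controls

Element activities are tested against the activity distribution of a
labeled negative-control group (at least 20 controls by default).  The
upper threshold is the percentile-p quantile (default 0.975, linear
interpolation) of control activities, the lower threshold the mirrored
quantile, and the shift their mean.  Activities are shifted by the
control mean before testing, which keeps the test valid when the whole
control distribution — and hence the threshold — sits below zero;
reported activities remain unshifted.  For the activating direction the
p-value is P(T ≥ (β′ − τ)/se) with τ = upper − shift; repressing
mirrors it; the two-sided form is
P(T ≥ (|β′| − τ)/se) + P(T ≥ (|β′| + τ)/se), which reduces exactly to
the ordinary two-sided moderated test at τ = 0 (τ = 0 is therefore
allowed; only τ < 0 is a configuration error, indicating a percentile
too low for the control spread).  Conclusions are always relative to
the chosen control group, never absolute activity claims.

## Simulator

The generator mirrors the benchmark's study conditions and provides the
default test bed: 5000 variants in five equal effect groups with true
log2 fold changes −2, −0.5, 0, 0.5, 2 (alternative-allele RNA means
scaled by 0.25, 1/√2, 1, √2, 4); three base replicate templates each
duplicated twice, for six technical replicates.  Counts are drawn
NB(n, p) with n = μ²/(σ²−μ), p = n/(n+μ), which reproduces mean μ and
variance σ² exactly and requires overdispersion σ² > μ.

Templates replace the empirical per-sequence moments a real library
would provide.  Each variant gets one characteristic DNA and one RNA
abundance, log-uniform on 20–500 counts; per-replicate means multiply
it by a log-normal technical factor (log-scale SD 0.3, ≈ ±35%),
because a real sequence's per-replicate moments are strongly correlated
— drawing them independently produces replicate effects far larger than
real data and visibly distorts the aggregated analysis, whose null
p-values are uniform in practice.  Dispersion factors φ = σ²/μ are
log-uniform on 1.5–10 per variant, replicate, and channel; barcode
multiplicity is uniform on 10–60 and shared between the alleles of a
variant.  Reference and alternative DNA counts are identically
distributed; alternative RNA preserves the template's dispersion factor
at the scaled mean (the variance at the scaled mean is not otherwise
identified).  Barcodes are unique random 16-mers; everything is
bit-reproducible given the seed.

The outlier process multiplies the RNA count of a random fraction of
barcodes by 25 (rounded) in k replicates, with k drawn from
(0.85, 0.05, 0.04, 0.03, 0.02, 0.01) over 1–6 replicates and the k
replicates chosen uniformly; every modified cell is recorded in a
registry.

What the simulator does *not* emulate: sequence-driven barcode biases
(GC content, RNA-binding-protein sites), integration-site effects,
between-barcode abundance heterogeneity within a sequence (barcodes of
one variant are exchangeable here), and library-preparation artifacts.
Passing tests on this generator therefore demonstrate correctness of
the statistical machinery under its stated model, not performance on
any particular real library.

## Problem sizes and numerical choices

The standard validation study uses 5000 variants × 6 replicates
(≈ 2 × 10⁶ barcode count records, frames of 5000 × 720 cells); it
simulates in ~7 s and fits in ~2 s per mode on one CPU.  The outlier
robustness check repeats injection five times at fraction 0.1.  Unit
tests use 200-variant versions of the same conditions.  Tolerances:
effect-size recovery is asserted to ±0.1 (strong group) and ±0.05 (weak
group) — sampling error plus the small Jensen-type bias of log-scale
means at 20+ counts; the simulator's alt/ref RNA ratio to ±0.02 over
≥ 10⁵ draws; GLS must match dense linear-algebra oracles to 1e−8–1e−10.
Quantiles use linear interpolation throughout; LOWESS uses span 0.5
with a small delta for speed; the trend is clamped below by a floor of
1e−4 of its median magnitude to keep weights finite.

## Known limitations

- A single consensus ρ is shared by all rows; rows whose true
  replicate-effect share differs are mildly mis-scaled.  At aggregated
  resolution (12 observations per row) the consensus estimate is also
  shrunk toward zero, making the aggregated mode's null p-values
  slightly conservative — matching the behavior of the reference
  aggregated method, but worth knowing.
- The design matrix is fixed at intercept(+allele); multi-condition
  contrasts (e.g. between cell types) would need a design-matrix
  extension of `fit_variants`.
- The threshold test's two-sided form uses the upper threshold
  symmetrically on |β′|; with strongly skewed control distributions the
  directional one-sided tests are preferable (both quantiles are always
  reported).
- Barcode-to-oligo assignment, FASTQ processing, and anything upstream
  of count tables are out of scope.
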