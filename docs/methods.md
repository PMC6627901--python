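# Methods

## Scope and data flow

`basalscreen` models the computational core of a subtype-stratified drug
screen on HNSCC cell lines: expression cohorts with known subtype labels
are harmonized into a nearest-centroid basal predictor; cell lines
receive a consensus basal / non-basal call from two independent
expression panels; single-agent viability plates are reduced to
dose–response descriptors (IC50, AUC); two-drug matrices are scored
against the Bliss independence reference; and the calls, descriptors and
scores are related to each other and to mutation status with standard
association tests. Validation-assay arithmetic (2^−ΔΔCt qPCR
quantification, clonogenic plating efficiency and surviving fraction)
closes the loop. All inputs can be produced by the seeded synthetic-data
generators, so the full pipeline runs and is tested without any external
download.

## Subtype classification

Differential expression uses a moderated two-sample *t* (basal vs all
other subtypes) per cohort. Feature-wise variances are shrunk toward a
prior, `s̃² = (d₀s₀² + d·s²)/(d₀ + d)`, with the prior parameters
(d₀, s₀²) obtained by moment matching on the log sample variances: with
`z = log s²`, `Var[z] = ψ′(d/2) + ψ′(d₀/2)` up to the chi-square
sampling term, so d₀ comes from Newton inversion of the trigamma
function and s₀² from the mean of z after digamma correction. When the
observed variances are less dispersed than chi-square sampling alone
would produce, d₀ is taken as infinite and the fully pooled variance is
used (normal reference distribution). With fewer than 10 features the
prior cannot be estimated usefully and the ordinary *t* (d₀ = 0) is
used; `prior_df` forces either limit explicitly. Within each cohort,
p-values are Benjamini–Hochberg adjusted and genes kept at FDR 0.05
(configurable); the cross-cohort panel is the intersection of
per-cohort significant genes with a consistent sign of effect, ordered
by mean |log2 fold change|.

Cohorts are gene-wise standardized (population SD, divisor *n*; the
difference from the n−1 convention is far below every tolerance used at
the sample sizes involved) and column-bound over shared genes. Genes
with zero variance in any cohort are dropped and logged. Centroids are
per-subtype arithmetic means of the standardized profiles over the
selected panel; prediction is the argmax of Pearson correlation between
a sample profile and the centroids, which makes the call invariant to
any positive affine transform of the profile. Exact correlation ties are
broken by the centroid set's fixed subtype order and flagged.

The consensus rule over two panels: basal requires basal in both;
non-basal requires non-basal in both, or non-basal in one with the line
absent from the other. The remaining cases — discordant predictions, and
basal in one panel with the line absent from the other — are not covered
by that rule; they are assigned `unclassified` here and excluded from
downstream group comparisons. This is a deliberate conservative choice:
a single basal call without confirmation is treated as insufficient
evidence in either direction.

Marker evaluation scores each gene by log2 fold change (basal mean minus
non-basal mean) and by the ROC AUC of its expression as a basal
discriminator (rank/U-statistic form, ties counted half). A gene is
selected when both exceed their thresholds; the thresholds are free
parameters (defaults log2FC ≥ 1, AUC ≥ 0.8) because no canonical values
exist for this selection.

## Dose–response descriptors

Viability is `(signal − blank)/(control − blank)`, clipped to
[−0.05, 1.2] by default to admit slight blank-subtraction undershoot and
fluorescence overshoot; technical replicates are averaged before
fitting. The four-parameter logistic
`v(c) = bottom + (top − bottom)/(1 + (c/IC50)^h)` is fit by bounded
least squares on log10 concentration with deterministic multi-start:
Hill slope starts at {0.5, 1, 2}, the IC50 start is the tested
concentration whose viability is nearest the half-range; the start with
the smallest residual wins. Flat series (no detectable response) return
`converged=False` with the AUC still reported; a fitted IC50
extrapolated more than 10³-fold outside the tested range is likewise
flagged unconverged.

The response AUC is the trapezoidal integral of observed (not fitted)
viability over log10 molar concentration; `auc_norm` divides by the
log10 span so a fully unresponsive curve scores exactly 1. This
convention is defined here, by this package: AUC scales in published
screen tables are often not recoverable from the printed concentration
ranges, which is why the packaged reference tables are consumed as
fixed values and never re-derived from curves. On the package's own
convention, `auc_norm` is monotone non-increasing in potency and the fit
is invariant to concentration unit rescaling (IC50 rescales
accordingly); both are enforced as property tests.

## Bliss synergy

On the percentage-inhibition scale the Bliss reference for single-agent
inhibitions ya, yb is `ya + yb − ya·yb/100`. The score of a matrix is
the arithmetic mean of observed minus expected over all combination
cells (both doses > 0); missing cells are excluded and counted, and a
result with more than half of its combination cells missing is flagged
unreliable. No response-surface smoothing is applied — the score is
exactly the mean raw excess of the measured grid, which keeps the
statistic fully specified and linear: adding δ to every combination cell
adds δ to the score, and transposing the matrix (swapping drugs) leaves
it unchanged. Group contrasts of scores use the Welch *t* by default.

## Association tests

Welch is the default two-sample *t* because the screen groups are
unequal (10 vs 15); the pooled variant is available to probe
sensitivity. The 2×2 chi-squared applies the Yates continuity
correction, `Σ(max(|O−E|−0.5, 0))²/E`; on small screen-sized tables the
correction changes conclusions (e.g. p ≈ 0.044 vs ≈ 0.014 uncorrected on
a 6/10 vs 2/15 split), and the corrected form is the package's
convention for such tables, with Fisher's exact test available when
expected counts are small. Pathway enrichment is the upper-tail
hypergeometric probability P(X ≥ k).

Mutation–response association tests, per (gene, drug), mutated vs
wild-type AUC with the moderated *t*, moderating across the drug panel
(the features are the drugs, so the panel shares one variance prior per
gene). Genes with fewer than two mutated or two wild-type lines are
skipped and logged. A negative direction means lower AUC in mutated
lines, i.e. a sensitizing mutation; pairs with p below the flag
threshold (default 0.1) are flagged. Whether moderation should pool
across drugs, across genes, or not at all is an open design point; both
the moderated and plain variants are exposed, and the null calibration
of the default is tested (flag rate tracks the threshold over 200
seeded null screens).

## Assay quantification

ΔCt normalizes the target Ct to the arithmetic mean of the reference-gene
Cts — equivalent to geometric-mean normalization on the linear scale —
and the fold change is `2^−(ΔCt_treated − ΔCt_control)`, assuming exact
doubling per cycle (no efficiency correction). Plating efficiency is
untreated colonies per seeded cell; the surviving fraction divides
treated colonies per seeded cell by the plating efficiency, which makes
it invariant to seeding density when colony counts scale proportionally.
Replicates are pooled by summing counts before the ratios.

## Synthetic data: what it emulates, and what it does not

One root seed spawns independent, fixed-order substreams per generator
(expression, dose response, combinations, mutations, qPCR, clonogenic,
cell-line panels), so outputs are byte-reproducible and adding a
generator never perturbs existing ones. Combination matrices
additionally derive a per-(line, combination) substream from a CRC32
tag, so matrices are independent of generation order.

Defaults encode the screen's study conditions: subtype proportions
0.30/0.25/0.25/0.20 (basal ≈ 30% of tumors), three cohorts of 60
samples, 200 genes of which each subtype up-regulates a 20-gene
signature by 2.0 log2 units (the basal signature headed by EREG and
AREG) under 0.5 log2 noise, per-cohort multiplicative batch scale in
[0.8, 1.25] plus a Gaussian offset; 13-concentration 2.5-fold dilution
series (small molecules 0.5 nM–30 µM; antibody ranges offset
accordingly) in technical triplicate with 2% signal noise, basal lines
10-fold more potent (log10 IC50 −1) for EGFR-directed drugs; 6×6
combination grids that are Bliss-consistent except for an injected
excess of 10/8/8 percentage points in basal lines for the
Cetuximab+Trastuzumab, Afatinib+Trastuzumab and Afatinib+Gedatolisib
combinations; CDKN2A-like mutation rates of 0.6 (basal) vs 0.133
(non-basal); binomial colony counts; noise-free Ct encoding by default.
The signature size and noise scales are this package's choices where no
external value exists; they are config fields and trivially overridden.

The generators emulate the *statistical structure* the analysis assumes
— not real biology. Expression is Gaussian with additive subtype shifts
and affine batch effects; there is no gene–gene correlation, no
HPV/anatomical-site confounding, no platform-specific distributions.
Dose–response noise is homoscedastic Gaussian on the signal; no plate,
edge-well or passage effects. Combination matrices are exactly
Bliss-plus-constant, so a nonzero score is synergy by construction
rather than pharmacology. Passing tests therefore demonstrate that each
stage recovers what its generator injected at the stated noise — an
internal-consistency guarantee, not evidence about real cohorts.
Cohort-scale results (ROC AUCs near 0.9 for AREG/EREG on ~100 tumors,
a specific 18-gene signature) require the real data and are
out of scope; the synthetic tests check the same machinery structurally
(ANOVA detects the marker shift at p < 0.001; injected markers score
ROC AUC > 0.9).

## Numerical choices and degenerate inputs

Fits are bounded (top ∈ [0, 1.5], bottom ∈ [−0.2, 1], Hill ∈
[0.01, 10], log10 IC50 within ±3 of the tested range) and
deterministic. Standardization divisor is n (population SD). Zero-margin
contingency tables, singleton ANOVA groups, zero-variance profiles,
both-absent consensus inputs, and missing single-agent axes raise
errors naming the offending input rather than propagating NaN. BH
adjustment, Pearson correlations and ROC AUC delegate to
statsmodels/scipy/scikit-learn; brute-force re-implementations serve as
oracles in the test suite only.

## Problem sizes

The shipped configuration runs the whole pipeline in a few seconds: 3
cohorts × 60 samples × 200 genes, 25 cell lines × 6 drugs × 13
concentrations × 3 replicates, 25 × 9 combination matrices of 6×6, and
the calibration suites (2000 null features for the moderated *t*; 200
seeded null screens for the mutation-association flag rate; 20–100
seeded replicates for accuracy and selection properties). These sizes
were chosen so the complete evidence base regenerates from scratch on a
single CPU in well under a minute per suite while keeping Monte Carlo
standard errors small relative to every asserted tolerance.

## Known limitations

- The AUC convention (trapezoid over log10 M, observed viabilities) is
  internally consistent but not comparable across packages or to
  published tables computed with unknown conventions.
- The Bliss score averages raw excess; surface-fitting scorers
  (e.g. SynergyFinder-style smoothing) will give different numbers on
  noisy matrices.
- The moderated *t*'s prior estimation assumes a common variance model
  across features; with very few features it falls back to the ordinary
  *t* rather than estimating an unstable prior.
- The consensus rule's `unclassified` category is this package's
  extension for cases the basal/non-basal rule does not define;
  downstream analyses simply exclude such lines.
- qPCR quantification assumes amplification efficiency exactly 2;
  standard-curve efficiency correction is not implemented.
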