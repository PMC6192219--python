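# Methods

This note documents the generative model, the algorithms, the parameter
choices that matter, and what the synthetic benchmark does and does not
show about real methylation-array data.

## The prediction model

Both clocks are linear predictors on CpG beta values. The pan-tissue
style clock predicts on a transformed age scale

    F(age) = log(age + 1) - log(adult_age + 1)   for age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1) for age >  adult_age

with `adult_age = 20` years (the conventional knot for this clock family;
configurable). F is continuous, strictly increasing and zero at the knot,
and its exact inverse maps predicted scores back to years. The
blood-style clock predicts age directly (`use_transform=False`).

Prediction is a fixed pipeline: (1) clock CpGs absent from the input —
whether platform-absent rows or per-sample missing values — are imputed
with the clock's gold-standard means (deterministic; no KNN branch, so a
single sample predicts identically to a cohort member and results are
reproducible); (2) optionally, each sample's clock-CpG beta distribution
is calibrated to the gold-standard profile (below); (3) the linear score
is formed and anti-transformed. Per-sample imputation counts and
calibration flags are attached to every output.

## Beta-mixture quantile calibration

The calibration step fits a three-component beta mixture by EM to the
sample's clock betas and to the gold-standard profile, then transports
each value through the monotone quantile map `Q_gold(F_sample(x))`
between the two fitted mixtures. Numerical choices:

* betas clipped to `[1e-6, 1 - 1e-6]` before fitting;
* deterministic initialization from value terciles; M-step by weighted
  method of moments (shape parameters clamped to `[0.01, 1e4]`);
* log-likelihood tolerance `1e-6` (relative), iteration cap 1000 — the
  moment M-step approaches the tolerance geometrically and routinely needs
  several hundred iterations on 353-point profiles, so a small cap would
  spuriously trigger the fallback;
* a sample whose EM does not converge falls back to the identity map and
  is logged and flagged, never silently calibrated;
* the quantile map is evaluated on a 4001-point grid with monotonicity
  enforced before inversion; with fewer than 30 observed clock CpGs the
  step is skipped with a warning (a 3-component mixture on fewer points is
  not meaningfully estimable).

A sample equal to the gold-standard profile is a fixed point of the map
(to < 0.01, limited by grid interpolation), and a profile shifted away
from the gold standard is pulled back toward it — both are asserted in
the test suite.

## The synthetic cohort

The generator defines the benchmark's study conditions; defaults are the
benchmarked design: 172 subjects with ages uniform on 19–50 years, a
353-CpG pan-tissue-style clock of which 19 CpGs are absent from the
second platform, a 71-CpG blood-style clock missing 6, 59 trimodal SNP
identity probes, 300 age-invariant CpGs and 12 technical replicate pairs.

Clock CpG j has mean beta `logistic(a_j + b_j * F(age))` with per-probe
intercepts `a_j ~ U(-1.5, 1.5)` and slopes `b_j = ±U(0.25, 0.9)` drawn
once per clock; cohort betas add truncated Gaussian noise with
`beta_noise_sd = 0.02`. Putting the age effect on the F scale means every
simulation exercises the transform/anti-transform path. Invariant CpGs
are constant per probe at `Beta(0.5, 0.5)` levels (bimodal, like real
array beta distributions); SNP probes take genotype values 0 / 0.5 / 1
with equal probabilities (identity checking needs variability, not
population realism).

The bundled clock definitions are **fitted, not hard-coded**: a separate
noiseless calibration cohort (`max(2 * n_cpgs, 400)` subjects) is drawn
from the same generative model and the target scale is regressed on the
betas by ridge regression with a tiny penalty (`alpha = 1e-6 * n_cal`).
The 353 logistic regressors are functions of the single variable F and
hence massively collinear; the small ridge penalty keeps coefficient
norms bounded (hence noise-robust prediction) while still interpolating
the calibration cohort far below the clock's own error — on noise-free
cohort betas the fitted clock reproduces true ages to < 0.5 years
(typically < 0.05). Gold-standard means are the calibration-cohort mean
betas, which makes imputation and calibration self-consistent with the
generative model.

## The intensity model

Observed fluorescence is signal plus background:

    X = signal_scale * beta * dye(channel) * T + B,
    T = 1 + temper * (E - 1),  E ~ Exp(1),     B ~ N(bg_mean, bg_sd) truncated at 0

with `signal_scale = 3000`, `bg_mean = 500`, `bg_sd = 100` fluorescence
units and `temper = 0.2` (a 20% intensity coefficient of variation; the
`temper = 0` limit is noise-free and recovers betas exactly). The
unmethylated read uses `1 - beta`. Type I probes read both alleles in
their design channel (so dye bias cancels in their betas); type II probes
read methylated in green and unmethylated in red (so the default green
bias of 1.2 shifts their betas — the reason a dye correction exists).
Out-of-band and negative-control entries carry background draws only;
normalization controls carry a fixed signal level per channel so the dye
bias is estimable. Technical replicates re-measure a sample's every
intensity under independent multiplicative `exp(N(0, 0.05))` noise.

Background Normal + signal Exponential-tempered was chosen deliberately:
it matches the noob model's assumptions, so the background-correction
oracle test (corrected betas must beat raw betas in RMSE against ground
truth) is a fair test of the implementation rather than of a model
mismatch.

## Preprocessing methods

* **raw** — betas straight from `M / (M + U + 100)`. The offset 100 is
  the Illumina convention (configurable); with a positive offset betas
  lie in `[0, 1)` and are monotone in M.
* **noob** — per sample and channel, `mu_b`/`sigma_b` from the OOB draws
  (minimum 30 draws enforced), `alpha = max(mean(observed) - mu_b, 1)`
  (plug-in moment rule; MLE out of scope), each in-band intensity
  replaced by the normexp posterior mean, computed via `log_ndtr` so the
  deep background tail cannot underflow; then dye correction scaling the
  green channel to match red-channel normalization-control means.
  Dye correction is applied after background correction.
* **quantile** — design-type-stratified quantile normalization of betas
  across samples (type I and II chemistries have different beta
  distributions and are normalized separately). The reference is the
  across-sample mean quantile function; ties receive averaged ranks;
  missing entries stay missing and do not contribute. This reduces the
  full stratified machinery of the common R implementation to its core,
  which is sufficient because the evaluation layer, not the normalizer,
  is the subject under test.
* **gs** — an *emulation* of GenomeStudio's proprietary color
  correction/background subtraction, implemented as the shift-and-scale
  normalization it is described as performing: subtract the per-channel
  negative-control mean (floored at 1 fluorescence unit), then equalize
  normalization-control means across channels. Its parameters are
  configurable precisely because the original's settings are not public.

noob and gs are strictly per-sample operations (adding a sample never
changes another sample's output — tested); quantile is the only
cross-sample method.

## Evaluation layer

Agreement between estimate vectors is summarized by Pearson r (two-sided
p), R², and the median absolute difference; undefined correlations
(zero variance) are reported as such, never silently dropped. The two
age-acceleration measures are the raw difference and the OLS residual of
DNAm age on chronological age (intercept included, so residuals sum to
zero and are exactly invariant to constant shifts — the property that
makes the residual the preprocessing-robust measure, asserted at 1e-8).
Pairwise preprocessing comparisons use a paired two-sided t-test with
Holm adjustment (Wilcoxon signed-rank pluggable); metric vectors that are
numerically identical (max |delta| < 1e-8 relative to scale) short-circuit
to p = 1 rather than t-testing float residue. Kendall tau comes from
scipy (tau-b) and is verified against an exhaustive all-pairs oracle.
Probe-wise cross-platform correlations use natural-log betas floored at
1e-6 (Pearson r is base-invariant; the floor only matters at 0), with
"beta range" operationalized as max minus min of raw betas pooled over
both platforms, and bin counts at r ≤ 0.2, > 0.5, > 0.8. Replicate
concordance reports each within-pair absolute DNAm-age difference and the
per-condition median. In cross-platform regressions both directions
(B ~ A and A ~ B) change only the fitted line, never r; the report stores
the estimate vectors so either can be drawn.

## What passing tests do and do not show

The generator reproduces the *structure* the analysis assumes —
age-dependent CpGs, additive background, dye bias, probe dropout,
replicate noise — but real cohorts have lower clock-CpG signal-to-noise,
cell-composition effects, batch/chip-position structure and
SNP-under-probe artifacts, none of which are simulated. Synthetic
cross-platform correlations (~0.98–0.99) are therefore tighter than the
0.91–0.96 typical of real two-platform comparisons, and replicate medians
(~0.25 y at the default replicate noise) are smaller than real-world
replicate errors of 2–3 y; it is the *orderings and contrasts* that the
benchmark asserts (background correction beats raw; the reduced clock
tracks the full clock; the residual measure shrugs off shifts the
difference measure inherits; replicate error grows monotonically with
injected noise; gs/noob replicate more tightly than raw), not the real
cohorts' absolute values. The distributional form of cohort betas is an
assumption, recorded here, not a fitted description of any dataset.

## Degenerate inputs and tie-breaks

Zero observed clock CpGs raise an explicit error ("no observed clock
CpGs"), as does a constant chronological-age vector for the residual
measure; single-sample quantile normalization is the identity with a
warning; singleton replicate groups are warned about and skipped;
zero-variance SNP vectors are flagged unevaluable rather than matched;
probes requested for dropping but absent warn rather than fail, so one
absence list serves matrices at any subsetting stage. All file loaders
reject malformed input (duplicate probe IDs, missing columns,
non-numeric ages) with errors naming the offending row.

## Problem sizes

Default study scale is the benchmarked design (172 subjects + 12
replicate pairs, 353 + 71 clock CpGs, 300 invariant CpGs, 59 SNP probes,
two platforms, four preprocessing methods); the full acceptance run
completes in about two minutes on one CPU. Unit and property tests use
smaller cohorts (8–200 subjects) chosen so each property is tested at the
smallest size where it is meaningful.
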