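# Methods

## The modeling problem

Given an injection × peak intensity matrix X (each sample injected in
triplicate) and a per-sample sensory score y for one attribute, we fit a
single-response OPLS model and judge it by replicate-grouped
cross-validation. Scores are the post-QC arithmetic means over panelists
and rounds; for fitting, each sample's mean is broadcast to its
injections, so X retains replicate-level information while y is constant
within a sample.

## Preprocessing

**Zero-maximum filter.** A peak whose maximum intensity over all
injections is zero carries no signal and is dropped first.

**Replicate-CV filter.** For each peak and sample, CV = 100·sd/mean over
the sample's replicate injections (sd with n−1 denominator). A peak is
removed iff its worst-sample CV is ≥ the threshold (default 10%,
inclusive). A sample whose replicate mean is zero makes the CV undefined;
we treat it as infinite, forcing removal — the conservative reading for a
peak that vanishes in some samples. Filters are idempotent and applied in
a fixed order (zero-maximum, then CV).

**Annotation.** A library entry is a candidate for a peak iff
|Δrt| ≤ 0.1 min and |Δm/z| ≤ 0.007 Da (inclusive comparisons; a flag
switches to strict). Among candidates the assignment minimizes the
normalized combined distance |Δrt|/rt_tol + |Δmz|/mz_tol, ties broken by
compound name; all candidates are retained for inspection.

**Extra variables.** Per-sample general properties are appended as
pseudo-peak columns, broadcast over each sample's injections; they carry
no rt/mz metadata and are excluded from cross-year peak matching.

## Sensory QC

Outliers are identified per (sample, attribute) group, pooling panelists
and rounds: quartiles by linear interpolation, Tukey fences at
Q1/Q3 ∓/± 1.5·IQR, whiskers anchored at the most extreme observations
inside the fences, records strictly outside the whiskers removed in one
pass (no iteration). Groups with fewer than four scores pass through.
Attributes are then screened by one-way fixed-effects ANOVA with sample
as the factor; an attribute is modeled only if p < 0.05. Degenerate
cases are handled explicitly: zero within-group variance with non-zero
between-group variance gives F = ∞, p = 0; identical group means give
F = 0, p = 1.

## OPLS (NIPALS, single response)

Both X and y are UV-scaled (mean 0, unit variance, n−1 sd; constant
variables are dropped and logged). With w ∝ Xᵀy (unit norm), t = Xw,
p = Xᵀt/(tᵀt), each orthogonal round extracts
w_o ∝ p − (wᵀp)w (normalized), t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o) and
deflates X ← X − t_o p_oᵀ. After `n_ortho` rounds the predictive
component is fitted on the deflated matrix; predictions are ŷ = t·c
back-transformed through the y scaling. By construction t_oᵀy = 0 and
tᵀt_o = 0 (checked to 1e-8). With zero orthogonal components the
estimator is exactly one-component PLS1 (verified against scikit-learn in
the tests). Component counts are reported as `1 + k + 0` — one
predictive, k X-orthogonal, zero y-orthogonal (single-column y admits
none).

R² is computed on the scaled response; RMSE on the original score scale
with denominator n (configurable; the convention is not universal).

## Cross-validation and Q²

Folds are built over samples, not injections: samples are shuffled by the
seed and dealt round-robin into k = 7 folds (sizes differ by ≤ 1), and
every injection follows its sample. Per fold, scaling parameters and the
OPLS fit use the training injections only; held-out y values are scaled
by the training fold's parameters. Q² = 1 − PRESS/SS with both sums
accumulated over held-out blocks. In-fold re-scaling avoids leakage of
the held-out samples' means into the scaling; `scale_in_fold=False`
reproduces the global-scaling convention of commercial software. A
caveat of in-fold re-scaling: Q² is then measured on a slightly different
scale per fold, and on easy problems it can exceed the in-sample R² by a
few hundredths; under global scaling Q² ≤ R² holds.

## Component selection, permutation validation, CV-ANOVA

The orthogonal-component count is chosen by forward search from zero,
accepting another component only while Q² strictly increases (the search
trace is kept). The chosen configuration is then validated with a
permutation test: y is re-assigned across samples n = 100 times (each
sample's injections keep their permuted value, preserving the replicate
structure), the model is refitted with the same components and folds, and
R², Q² and |r(y_perm, y)| recorded. Least-squares lines through the
permuted cloud plus the unpermuted anchor at correlation 1 give the R²
and Q² intercepts. A configuration is **valid** when R²-intercept < 0.3,
Q²-intercept < −0.05, *and* the unpermuted Q² exceeds every permuted Q².
The third condition is essential: for a no-signal model the anchor sits
inside the cloud and both intercept criteria pass trivially, so the
intercepts alone cannot reject a null model. The full cloud is always
serialized so alternative readings (e.g. per-permutation thresholds) can
be applied afterwards. If validation fails, orthogonal components are
removed one at a time and the test repeated; a model that never validates
is returned at zero components, flagged invalid.

CV-ANOVA compares the cross-validated predictive residuals against the
total response variation: F = ((SS − PRESS)/a) / (PRESS/(n − a − 1)) with
a = total components and n = injections; p from the F distribution.

## Signed VIPpred

With a single predictive component and unit-norm w, the VIP over the
predictive component reduces to vip_j = √p·|w_j|, so mean(vip²) = 1 —
an identity asserted for every fitted model. Each variable's sign is the
sign of its Pearson correlation with the attribute's sample means
(sensory scores exist per sample, so the correlation is computed on
sample-level means, not injections); zero-variance variables get sign 0
and are never selected. Selection uses the strict rule VIPpred > 1.5.

## Transfer validation

Peaks are paired across datasets by mutual nearest match within the
annotation tolerances (normalized distance; ties reported). Applying a
model to another year scales the target X and y with the **training
model's** parameters — no re-centering on the target, which is the only
choice that treats the target year as unknown. We report both
R²_validation = 1 − SS_res/SS_tot (coefficient of determination on the
model-scaled target response; can be negative) and the squared-correlation
variant, since conventions differ. Variables with |signed VIPpred| > 1.5
in both years feed reduced models, refitted per year with the same
component-selection/validation pipeline and cross-predicted again; an
empty common set produces an explicit skip record. The cross-year
attribute correspondence is user-declared, never inferred.

## The synthetic generator

The generator emulates the study design the pipeline assumes, with
defaults matching the larger of the two emulated brewing years: 40
samples × 3 injections, 430 informative peaks plus 5 planted zero-maximum
and 20 planted high-CV peaks, 26 panelists × 3 rounds, 5 attributes with
5 driver peaks each.

**Peak intensities** are log-normal per peak per sample (log₁₀ location
U(3, 6), spread U(0.10, 0.30)). Between-sample variation follows a latent
factor model: one global "strength" factor loading on every informative
peak (variance share 0.25) plus one of 8 block factors (0.70), plus an
idiosyncratic residual (0.05). This mimics the strong mutual correlation of
real metabolome peaks — co-regulated metabolites, adducts and in-source
fragments — and is what makes the benchmark realistic: with independent
peaks, a 430-variable model fitted on ≤ 40 samples cannot transfer to new
samples and its permuted-R² intercept is structurally high, so both the
transfer and the permutation behavior of the real analysis would be
unreproducible. The three variance shares were calibrated once, by
simulation, to sit in the regime where the real study's qualitative
outcomes (permutation validity, VIP selection counts of ~40–80 of 430,
transfer R² ≈ 0.5+) hold, and then frozen.

**Replicate noise** is multiplicative with the deviation vector centered
and rescaled so each (peak, sample) cell's empirical CV equals its drawn
target (U(2%, 8%) at the default 5% setting) — guaranteeing that no
informative peak trips the 10% filter by sampling accident. Each planted
high-CV peak gets one sample with CV drawn in [12%, 25%].

**Sensory scores.** Each attribute's sample expectation is an affine
function of the standardized sample-mean intensities of its driver peaks
(weights of common sign per attribute, magnitudes U(0.8, 1.2)), scaled so
that ±2 sd of the signal fits inside the scale interior after reserving a
margin for noise, then clipped to that interior. Panelist bias is
bimodal: half the panel scores −b, half +b (b = `panelist_bias_sd`),
modeling strict and lenient judges; round noise is uniform with sd
`noise_sd`. With the default b = √3·noise_sd the clean score
distribution of each (sample, attribute) group is flat-topped and
bounded, so its Tukey fences sit far outside the clean support — clean
records are never flagged, and the injected outliers (displaced beyond
the group extreme by 3·IQR + 1, exempt from clipping) are exactly the
records the QC removes. With Gaussian noise this exact recoverability is
impossible (natural Tukey outliers arise at ~0.7% per record).

**What the generator does not emulate:** chromatographic drift,
ionization suppression, batch effects, panelist drift across rounds,
scale-use differences beyond a constant bias, or heavy-tailed score
noise. Passing the end-to-end checks therefore demonstrates that the
implementation is correct and well calibrated under the assumed data
structure, not that the method is robust to those real-world artifacts.

## Numerical choices and degenerate inputs

- Zero-variance variables are dropped at scaling time (globally or within
  a CV fold) and recorded.
- Orthogonal extraction stops when the candidate w_o norm falls below
  1e-10 (no y-orthogonal structure left); requesting more components than
  extractable raises.
- A constant response raises everywhere (scaling is undefined).
- Quantiles use linear interpolation (configurable at the call level);
  annotation ties break lexicographically; fold assignment is
  deterministic given the seed; one root seed drives per-module
  substreams so a change in one module's draw count does not shift the
  others.

## Problem sizes in the test suite

The acceptance tests run the study-size conditions (455 peaks, 40
samples) with 10–100 seeds per check, and the unit tests use a
scaled-down study (60 peaks, 16 samples, 8 panelists); the acceptance
script uses 10–30 studies per quantity. These sizes give stable medians
and rates while keeping the default test run and the acceptance script
fast enough for routine use.
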