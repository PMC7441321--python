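# Methods

This note documents the statistical procedures implemented in `npnorm`,
the defaults chosen where the methodology left a decision open, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Scaled scores (`npnorm.norm_tables`)

Raw scores are rank-normalised within a normative sample. We use Hazen
fractional ranks r_i = (rank − ½)/n with mid-ranks for ties; the
literature on normalized scaled scores uses several plotting-position
constants and does not fix one, and Hazen is symmetric and standard in
normative work. Ranks are oriented so that better performance (faster
time on GP-DH, GP-NDH, TMT-A and CTT1; higher counts elsewhere) gets the
higher rank, then ss = round(10 + 3·Φ⁻¹(r)) clipped to [1, 19], giving an
integer scale with mean 10, SD 3 in the normative sample.

Lookup tables store inclusive integer bins exactly as published. Lookup
is by bin lower bounds, so a non-integer raw falling in the one-unit gap
between printed bins resolves to the lower bin; raw values beyond the
extreme bins clamp to the nearest extreme scaled score with a warning
record rather than an error, because clinical data contain extremes and
silently dropping them would bias impairment rates. Tables built by
`build_scaled_table` extend bin edges to the midpoints between adjacent
score groups so the covered range is contiguous. Degenerate samples
(all raw values identical) produce a single bin at ss = 10 with a
warning. The minimum sample size defaults to 50.

## T scores (`npnorm.tscore`)

T = 50 + 10·(ss − ŝs)/σ̂ with ŝs a fractional polynomial in
edu_t = (edu+1)/10, age_t = age/100 and male. The +1 and the /10, /100
scalings are fixed constants (not auto-scaled): they keep the transforms
strictly positive at edu = 0 and match the published coefficients'
scale. The shipped formula file reproduces the published set coefficient
for coefficient and is covered by a golden-file test.

Choices:

* T scores are neither truncated nor rounded internally; reports round
  to 1 decimal. Whether extreme T should be truncated before deficit
  conversion is not specified anywhere we could verify, so the default is
  no truncation.
* Education is validated against the normed range (0–21 years) and age
  against 18–64; out-of-range values warn but the formula is still
  evaluated as published, since extrapolation is the clinician's call.
* Domain summary T scores are unweighted means of the component T scores
  (motor: 2 tests, SIP: 6) and require every component. The published
  summary Ns are smaller than the individual-test Ns, which is consistent
  with listwise completeness; partial averages would change the summary's
  variance and are not computed by default.

## MFP norm refitting (`npnorm.mfp`)

The functional form of education and age is selected by the
Royston–Altman closed test over the conventional power set
S = {−2, −1, −½, 0, ½, 1, 2, 3} (0 = log; repeated power p gives x^p and
x^p·log x), maximum degree 2, using Gaussian deviance n·log(RSS/n) and
χ² reference distributions with the conventional FP degrees of freedom
(4 for FP2 vs null, 3 vs linear, 2 vs FP1). Defaults the methodology
does not pin down, and why we chose them:

* α = 0.05 — the customary default of the mfp software family.
* All three demographics forced, sex always linear — every published
  formula contains all three covariates, and sex is binary.
* Selection cycles over education then age, each adjusted for the
  other's current form, until the forms stabilise (≤ 5 cycles). Whether
  the original fits cycled or did one pass per covariate is unknown;
  with only two continuous covariates both almost always agree, and
  cycling is the standard MFP algorithm.

The final model is refit by ordinary least squares (numpy lstsq; the fit
is deterministic) and residual_sd is the degrees-of-freedom-corrected
root mean squared residual, √(RSS/(n − p)). Consequences:

* Self-norming: T computed from a formula on its own fitting sample has
  mean exactly 50 (the OLS residuals sum to zero); the SD is slightly
  below 10 by the factor √((n − p)/(n − 1)) ≈ 0.998 at n = 1200 — the
  tests document this offset.
* The closed test's complexity is monotone in α: lowering α can only
  move the selection toward simpler forms (property-tested).
* At α = 0.05 a forced covariate with truly linear effect is upgraded to
  an FP form in about 5% of samples, by construction. The recovery tests
  therefore fix seeds and check the typical (linear) outcome.

## Deficit scores and impairment (`npnorm.deficit`)

The T → deficit mapping is the standard global-deficit-score recoding:
T ≥ 40 → 0, 35–39.99 → 1, 30–34.99 → 2, 25–29.99 → 3, 20–24.99 → 4,
T < 20 → 5. The breakpoints live in a single module-level table
(`DEFICIT_BREAKPOINTS`) so an alternative convention can be swapped in
without touching code. Test-level impairment is deficit ≥ 1 (equivalently
T < 40); domain impairment requires the mean component deficit to exceed
0.5 strictly, so two tests with deficits {0, 1} (mean exactly 0.5) are
not domain-impaired. Domains use the same component sets as the summary
T scores and require completeness.

Under independent T ~ Normal(50, 10), test-level impairment is
Φ(−1) ≈ 15.9% and the two-test domain rate ≈ 7.6%; the test suite checks
the classifier against a brute-force Monte-Carlo oracle.

## Group statistics (`npnorm.analysis`)

* Cohen's d uses the pooled SD; its default CI uses the normal
  approximation SE(d) = √(1/n₁ + 1/n₂ + d²/(2(n₁+n₂))), which matches
  the published intervals to about ±0.01; exact noncentral-t intervals
  are available behind a flag. The p-value is the pooled two-sample t
  test, which is identical to the univariable regression on the group
  indicator (equivalence-tested).
* Odds ratios use Wald CIs on the log scale, exp(log OR ± 1.96·√Σ1/cell),
  validated against the published intervals; zero cells raise unless the
  0.5 continuity correction is enabled. The OR p-value is the Wald z
  test, asymptotically the logistic-regression group test.
* BH FDR adjustment delegates to statsmodels' step-up implementation
  behind `bh_adjust`, with the family size k passed explicitly because
  the study corrects the 8 individual tests and the 2 domain summaries
  as separate families; a brute-force implementation of the step-up
  definition serves as the independent oracle in the tests.
* Fisher's exact test (demographic categorical comparisons) is scipy's
  hypergeometric two-sided point-probability implementation.
* Missing data: listwise deletion per analysis, mirroring the varying
  per-test Ns in the published tables.
* Demographic gender/age/education effects are reported from both the
  univariable and the multivariable model, since published coefficients
  do not state which model they came from.

Rounding for report parity: d and OR to 2 dp, p-values to 3 dp,
percentages to 1 dp.

## Synthetic cohorts (`npnorm.simulate`)

The generator's defaults are the study conditions: group sizes 363/320;
control age 34.3 (SD 10.6, range 18–64), case age 37.8 (SD 9.4, 18–60);
education 12.4 (4.2, 0–21) vs 9.6 (3.7, 2–20); male proportions
34.4%/22.2%; CD4 log-normal matched to median 405 with σ_log set from
the published IQR (246–574); detectable viral load with probability
0.428 and log₁₀ VL ~ Normal(4.61, 1.30) among detectable; ART status
53.6% on-ART / 44.5% naïve / 1.9% other. Age and education are integers,
as reported. Default per-test HIV effects are the published case-control
Cohen's d values; ART (+0.24 d) and CD4 (+0.22 d) shifts default to the
published summary-scale contrasts, the viral-load effect to 0 (none was
observed).

Effects are injected on the latent scaled/T scale — one configured d
unit equals one residual SD of the test — so configured effect sizes are
directly interpretable and recoverable; raw scores arise by rounding the
latent scaled score, clipping to the scores available in the conversion
table, and drawing an integer raw uniformly from that score's bin.
ART/CD4/VL shifts are mean-centred within the case group using their
configured prevalences, so the marginal case-control d stays at the
configured HIV effect while the subgroup contrasts equal the configured
shifts.

What the generator does **not** emulate, and hence what passing tests do
not show about real data:

* Tests are conditionally independent given demographics and group. Real
  test scores are positively correlated; the study's SIP summary SD
  (6.62) implies an average inter-test correlation near 0.35, whereas
  independent tests give SD ≈ 10/√6 ≈ 4.1. Domain summary SDs and domain
  impairment rates from synthetic data are therefore not comparable to
  the published ones, and the package reproduces those published
  quantities from the printed counts instead.
* Demographic effects on scores come from the shipped formulas
  themselves (optionally scaled), so refitting recovers them by
  construction; this validates the machinery, not the formulas.
* No missingness is simulated; published per-test Ns vary slightly.
* Rounding and clipping at the scaled-score extremes introduce small
  (≲ 0.25 T-unit) biases in group means relative to the configured
  effects, visible in the calibration tests' tolerances.

## Problem sizes and determinism

Simulation-based checks use: n = 2000 for coefficient recovery, n = 363
for normative T calibration, 200 replicates at n = 350 for FP power
recovery, 100 replicates for the closed-test null, 60 replicates of
study-sized cohorts for the null-FDR check, and 10⁵ draws for the
Monte-Carlo impairment oracle — sizes at which Monte-Carlo error is well
inside the asserted tolerances. All randomness flows through
numpy `default_rng` with fixed or caller-supplied seeds; the pipeline
itself is deterministic, and a fixed-seed cohort serialises
byte-identically.

## Known limitations

* Norms and conversion tables apply to Cameroonian adults aged 18–64
  with 0–21 years of education; outside that range the package warns
  and extrapolates the published formulas as printed.
* Only the two domains covered by the published standards (motor, SIP)
  are implemented; no global (7-domain) deficit score or HAND staging.
* The Wald OR interval and normal-approximation d interval are
  large-sample approximations; with very small cells prefer the exact
  machinery (`fisher_exact_2x2`, `noncentral_ci=True`).
* `build_scaled_table` reproduces the construction algorithm but any
  freshly built table reflects its input sample, not the published
  norms; the published tables are data, transcribed and
  contiguity-checked, not refittable from this package alone.
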