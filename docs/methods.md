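# Methods

## Variable derivation

A *consumption event* (CE) is the set of foods and beverages reported at
one unique clock time within one 24-h recall day. Event identity is exact
equality of the recorded occasion time — no time-window merging — because
the recall files already key items to an occasion time. NHANES times
arrive as seconds from midnight and are converted to fractional hours;
values ≥ 24 h are reduced modulo 24 with a logged warning.

Per day we compute intake totals (kcal, macronutrient grams, item grams,
food count) and intraday statistics: time of first CE, CE count, mean and
SD of *distinct* foods per CE (deduplicated by food code within the
event), SD and mean of successive time gaps in minutes (no wrap-around
across midnight; each day is self-contained), and the SD of per-CE energy.
All SDs are sample SDs (n−1) and are missing when fewer than two values
contribute. Day-level food counts for the interday difference default to
raw row counts (config switch for per-day deduplication), while the per-CE
diversity variables always deduplicate — mirroring the distinction between
"number of foods" and "distinct foods per CE" in the variable definitions.

Participants contribute one or two recall days; each variable is averaged
over the days on which it is defined (a SD defined on one day only passes
through unchanged). Interday-difference (IDD) variables are unsigned
absolute differences between the two days and are missing for one-day
participants; the IDD of the mean gap is missing when either day has fewer
than two events. The mean time gap itself is excluded from the outcome
set because it is fully determined by first-CE time, CE count, and the
day's eating span.

*Relative* macronutrients are residuals from pooled OLS regressions of
each macronutrient's day-averaged grams on day-averaged total grams with
an intercept — a composition measure orthogonal to intake volume over the
pooled sample (correlation < 1e-10 by construction). Residualisation pools
all available participants (both genders when present), so subgroup means
need not be zero.

## Association stage

Three fixed outcome sets (5 amount, 6 intraday, 5 interday variables) are
each tested with a multivariate linear model of the set on FI status, with
and without covariates (age and poverty-income ratio continuous; education
and ethnicity as unordered factors; children in household binary). The FI
term is tested with Pillai's trace and its standard F approximation
(Wilks' lambda available; for a two-group predictor the two are the same
test). The multivariate machinery is implemented in-package on the SSCP
algebra so that weighted (WLS) fits are available; it is cross-checked
against `statsmodels.multivariate.MANOVA` in the test suite. Univariate
follow-up models are `statsmodels` OLS/WLS; with binary FI and no
covariates the coefficient is exactly the insecure-minus-secure mean
difference. Complete cases are taken per model, so denominators vary
across panels. No multiple-testing correction is applied, matching the
MANOVA-gatekeeper-then-univariate strategy.

Standardized estimates divide the adjusted coefficient by the outcome's
marginal SD (the predictor stays a 2-level contrast); CIs are
(B ± 1.96·se)/SD, rows sorted by unsigned magnitude. Weighted fits use the
configured survey weight with model-based standard errors; no
design-based (Taylor-linearised) variance is attempted — a documented
limitation, defensible because weighted and unweighted results are
expected to be essentially identical for these models.

## Mediation

Candidate mediators are variables that both respond to FI (adjusted) and
predict BMI (adjusted) with sign(B_BMI)·sign(B_FI) > 0, i.e. an indirect
path of the same sign as the positive FI→BMI association. The multiple
mediation model is the saturated recursive linear system fitted by least
squares on one common complete-case sample: mediator-on-FI a-paths, and
BMI on FI + mediators for c′ and the b-paths. For this system OLS path
estimates coincide with the SEM maximum-likelihood estimates, so a
general SEM engine is unnecessary; delta-method (Sobel) standard errors
reproduce the usual z statistics, and a seeded percentile bootstrap over
participants is available. The total effect is assembled from the identity
c = c′ + Σ aᵢbᵢ (its point estimate coincides exactly with the separate
total-effect regression on the same sample, which supplies its standard
error), so proportions mediated sum exactly. Proportions are reported as
percentages; when |c| is numerically zero they are undefined and flagged.
The default mediation fit is covariate-free (covariates can be supplied),
since the decomposition of interest is of the raw FI–BMI gap on the
mediation sample.

## Synthetic cohort generator

The generator emulates a two-recall-day survey cohort of women: cohort
size 3101 with 90.2% having any recall and 90.7% of those both days; FI
score 0–10 with 68% zeros and the remainder spread over three severity
bands; sociodemographic covariates drawn independently of FI (truncated
normals / categorical draws). Feature locations and scales follow the
reference population values (daily energy 1779 kcal sd ≈ 700; first CE
7.93 h; 5.57 CEs/day; gap SD 104.27 min; energy-per-CE SD ≈ 322 kcal), and
the default FI effect vector uses the reference unadjusted coefficients
(e.g. +16.15 min on gap SD, −1.49 foods/CE, −2.02 g fibre, +6.74 kcal
energy).

Distributional choices were made so injected additive effects are exact:

* positive latents (daily energy, gap SD, per-CE energy SD, foods-per-CE
  rate, daily grams) are **Gamma** with the configured mean and SD — the
  mean shifts exactly with FI, unlike a truncated normal;
* day-level noise is **unit-mean lognormal**, keeping day averages exact
  and giving a closed form for the expected unsigned interday difference,
  E|e^X − e^Y| = 2(2Φ(τ/√2) − 1) for iid log-SD τ — used to calibrate the
  interday energy difference per FI group;
* within a day, the (n−1) gaps between n events are a one-long-rest-short
  pattern with exact mean (span/(n−1), span = last-CE − first-CE draw) and
  exact sample SD equal to the drawn dispersion, at a random position;
  event energies use the same construction. The intraday SD variables are
  therefore injected exactly, and all event times stay inside the day;
* CE counts are 1 + Binomial(8, p) with participant-varying p; foods per
  CE are 1 + gamma-mixed Poisson (overdispersed); macronutrient grams are
  linear in total grams with FI composition shifts (carbohydrate up,
  protein/fat/fibre down) and fibre coupled to the carbohydrate deviation,
  keeping the residualisation meaningful;
* BMI = intercept + c′·FI + Σ bᵢ·mediatorᵢ + noise, where the mediators
  are the participant's *realized* derived values (the day-mean gap SD,
  day-mean foods per CE, and the pooled-residual relative fibre computed
  exactly as the pipeline computes it). Defaults give total effect 2.21
  with 14.5% mediated (4.2% gap SD, 2.9% foods per CE, 7.4% fibre).

Four features cannot take an independent additive shift because they are
emergent statistics of the same draws (SD of foods per CE; IDD of food
count, CE count and mean gap) — and the per-CE energy SD is occasionally
capped by day-level feasibility (event energies must stay positive).
`analytic_expectations` supplies their expected FI effects by large-n
Monte Carlo over the generator's own day-structure layer (default 2×10⁶
participants per group, two days each; simulation error well below the
recovery tolerances), and the injected shifts' expectations in closed
form. The plug-in mediation truth is Σaᵢbᵢ/(c′ + Σaᵢbᵢ).

What the generator does *not* emulate: FI–covariate confounding (adjusted
and unadjusted coefficients therefore coincide in expectation, and the
synthetic adjusted FI→BMI estimate sits near the raw gap rather than below
it); correlation structure among the amount variables (so the synthetic
MANOVA F's and the mean standardized estimate run larger than their
real-data analogues); day-of-week structure; food-code semantics or a
nutrient database; severity gradients across the four FI levels (effects
are binary secure/insecure). Its relative-fibre SD (~4.9 g) is below the
reference 6.6 g — the noise scales were chosen so the positivity floor
clips < 0.1% of days and leaves the injected fibre shift effectively
unbiased. Passing tests on this cohort demonstrate correctness of the
derivation, models and decomposition under known truth, not realism of
any particular real-world dataset.

## Numerical choices and problem sizes

Sample SDs are computed by a stable two-pass segmented algorithm; exact
agreement with a loop-based oracle is asserted at 1e-12 relative
tolerance. Residual orthogonality is asserted below 1e-10, the mediation
identity below 1e-8. Type-I calibration uses 1000 null cohorts of 2000
participants (rejection rates required within 0.05 ± 0.014, the two-sided
binomial band); parameter recovery uses 200 effectful cohorts of 3000
participants, requiring each expected FI effect and the proportion
mediated to lie within two Monte-Carlo standard errors of the replicate
mean. These sizes keep the full suite to a few minutes on one CPU while
leaving the binomial/MC bands meaningful. All simulation seeds are fixed
in the tests; the acceptance script takes its seed on the command line.

## Known limitations

Model-based (not survey-design) variances; no exposure–mediator
interaction or unmeasured-confounding sensitivity analysis; the NHANES
XPT path is translation-tested on in-memory frames only (transport files
cannot be fabricated portably in a text-only test fixture); the
food-security item mapping assumes the standard adult-module coding and
is configurable.
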