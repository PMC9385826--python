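# Methods

## Scenario bands

The scenario engine is deliberately simple: given a clinician's
estimate *m* of the median survival of a group of similar patients, the
bands are fixed multiples of *m*,

* worst-case: survival `< 0.25 m` (the ~90th percentile of an
  overall-survival curve is roughly a quarter of its median),
* most likely: `0.5 m` to `2 m` (the ~75th and ~25th percentiles),
* best-case: `≥ 3 m` (the ~10th percentile).

The multiple-of-median percentile approximations hold reasonably well
across typical advanced-cancer survival curves, which are
right-skewed; they are exact for no distribution, and the evaluation
machinery below exists precisely to check how they perform. Band
openness follows the verbal definitions: the worst-case band is open
above ("less than 3 months"), the most-likely band closed, the
best-case closed below ("36 months or longer"). Multipliers are
configuration (`MultiplierConfig`), not constants, so variant
approximations can be explored; the defaults are the values above and
the validity constraint is `0 < worst < ml_lower < 1 < ml_upper <
best`. The follow-up schedule re-checks vital status at `0.25, 0.5, 1,
2, 3.3, 5` times the estimate — early checks for short estimates,
sparse late checks for long ones, aligned with the band boundaries the
evaluation needs.

**Display rounding.** Bounds of at least 3 months are shown to the
nearest whole month; shorter bounds are shown in whole weeks
(months x 4.33), so a 0.5-month bound displays as "2 weeks" rather than
"0 months". Raw unrounded values are always carried in the summary's
machine-readable block, from which the exact `ScenarioSet` round-trips
(`parse_summary`). The narrative wording is original; scenarios are
presented most-likely first by default (the order most preferred by
patients who expressed a preference), and the order is configurable.

## The OST/EST ratio evaluation

For each patient the observed survival time (OST, consultation to
death or last follow-up) is divided by the estimated survival time
(EST). A patient alive at last follow-up gives a right-censored ratio
(last-known-alive time over EST). All accuracy metrics are
probabilities under the Kaplan–Meier distribution of the ratio, never
raw counts, so censoring cannot bias them downward:

* calibration: `P(ratio < 1)` and `P(ratio > 1)` — each near 0.5 when
  estimates are centrally unbiased;
* precision: `P(0.67 ≤ ratio ≤ 1.33)`;
* scenario coverage: `P(ratio ≤ 0.25)`, `P(0.5 ≤ ratio ≤ 2)`,
  `P(ratio ≥ 3)`. The bands do not partition the line (the gaps
  (0.25, 0.5) and (2, 3) are real), so the three coverages need not sum
  to 1.

Band endpoints are honoured exactly through left limits of the
survival function: for a closed band `[a, b]`,
`P = S(a⁻) − S(b)`, where `S(a⁻)` is the survival value at the largest
event time strictly below `a`; ratios tied exactly at a closed endpoint
count inside the band. Product-limit fitting is delegated to lifelines;
ties between deaths and censorings at the same ratio are resolved
deaths-first, the standard convention.

**Confidence intervals.** The default interval is a normal
approximation on the Greenwood standard error of the band probability,
truncated to [0, 1]. For `P = S(a) − S(b)` the variance uses the full
covariance of the product-limit estimator,
`Var = S_a²C_a + S_b²C_b − 2 S_a S_b C_a` with
`C(t) = Σ_{t_i ≤ t} d_i / (n_i (n_i − d_i))`, which collapses to the
binomial `p(1−p)/n` on uncensored data (a property the tests assert).
The original analyses of this design do not name their CI method and
their intervals are data-dependent, so the choice here is documented,
internally consistent, and switchable (`ci_method="wilson"` uses a
Wilson score interval on an effective count of `n_used` trials — a
cruder but more robust option at small n).

The model/results split follows the fit-and-summarise convention:
`RatioAccuracyModel(sample, precision_window, multipliers).fit()`
returns a `RatioAccuracyResults` with the six `ProportionEstimate`s,
the `KMCurve`, `summary()`, `to_json()` and a `plot()` of the ratio
distribution on a log axis.

## Agreement and association statistics

Likert agreement collapses to (agree + strongly agree) over all
non-missing responses; "unsure" is in the denominator only. Every
analysis excludes its own missing responses, so denominators vary by
question. Proportions get **Wilson score intervals**: recomputing a
published table of such intervals, Wilson reproduces 45 of 48 printed
whole-percent CI pairs exactly, while Clopper–Pearson, Jeffreys,
Agresti–Coull and Wald each break more rows; the three remaining rows
differ by one point in the upper bound under every standard method and
are tracked as known printing-level discrepancies in the tests.

Associations between baseline characteristics and agreement are
**unadjusted 2×2 Wald odds ratios**: `OR = ad/bc`,
`CI = exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`, two-sided p from the Wald z.
For a saturated univariable logistic regression these closed forms
coincide with the model-based estimates, which keeps every printed
digit exactly testable without an iterative fit. Any zero cell makes
OR, CI and p undefined (reported NA, no continuity correction). For
covariates with more than two levels each level is compared to the
reference and an overall p comes from the **likelihood-ratio (G) test**
of independence on the levels × outcome table — chosen over the Pearson
chi-square because the G-test reproduces published per-variable
p-values (e.g. a seven-level cancer-type table with a zero cell) that
Pearson does not, as expected when the original analysis was a
logistic-regression deviance test. Display rounding is half-up: ORs
and bounds below 1 to two decimals, 1–10 to one decimal, larger values
to whole numbers.

The **sample-size design** distinguishes two hypothetical true
proportions with a one-sample normal approximation:
`n₀ = ((z_α √(p₀q₀) + z_β √(p₁q₁)) / (p₁ − p₀))²`, rounded up and then
inflated by `1/(1 − attrition)`. With p₀ = 0.60, p₁ = 0.80, one-sided
α = 0.05, power 0.95 and 20% attrition this gives n = 68. The
published design statement mixes power and CI-separation language; a
two-independent-sample design cannot land near the published ~70, so
the one-sample reading is implemented and stated here.

## Instruments

Scoring structure ships as YAML (`data/instruments.yaml`); item
wordings are licensed and not included.

| id    | items | scale | reversed | scored | total range | default target median |
|-------|-------|-------|----------|--------|-------------|-----------------------|
| stai6 | 6     | 1–4   | 1, 4, 5  | all    | 6–24        | 13 |
| hhi   | 12    | 1–4   | 3, 6     | all    | 12–48       | 38 |
| lotr  | 10    | 0–4   | 3, 7, 9  | 1,3,4,7,9,10 | 0–24 | 16 |

The stai6 total is the raw 6–24 sum, not the ×20/6 prorated variant —
the published median of 13 is only attainable on the raw scale. Reverse
coding maps `r → min + max − r` (an involution). A missing scored item
leaves the total missing; missing fillers are harmless. Median splits
default to ties-below (keeping the "below median" reference group
non-empty under heavy ties) and, for even n, the lower central order
statistic (an attainable integer score); both conventions are
configurable because published analyses rarely state them.

## The synthetic cohort

The simulator emulates the structure of a prognosis-consultation
cohort, not any particular patient set:

* **EST** is log-uniform on (2, 96) months — the published range of
  estimates; its median (≈13.9 months) approximates the published
  median of 12 without attempting to match the unpublished full
  distribution.
* **True survival** is drawn with median `EST × median_bias`
  (`median_bias = 1` is a perfectly calibrated clinician). Families:
  log-normal (default, σ = ln2/Φ⁻¹(0.75) ≈ 1.0276 so that the
  most-likely band holds exactly half the mass and calibration is
  exactly 0.5), exponential (band masses 1−2^−0.25 ≈ 0.159,
  2^−0.5 − 2^−2 ≈ 0.457, 2^−3 = 0.125), and Weibull. `oracle()` returns
  these probabilities analytically for any band — the independent check
  on the whole evaluation pipeline.
* **Censoring** is administrative at a single horizon (none by
  default; 43 months — a realistic maximum follow-up — yields roughly
  20% censoring under the defaults). Because the horizon applies to
  calendar time and EST is independent of the ratio, the induced
  censoring of the ratio is independent of it, so KM band estimates
  remain consistent — a property the tests verify at n = 30 000.
* **Questionnaires**: a per-question Bernoulli agreement probability
  (defaults matched to typical published agreement levels), with a
  planted log-odds effect (default ln 5.7) raising agreement with the
  primary "helpful" item for patients whose hope score exceeds the
  sample median; the below-median baseline defaults to 58/68. About a
  third of patients return no questionnaire, and 3% of individual items
  are missing, reproducing realistic varying denominators. 7/222 of
  patients lose survival follow-up entirely.
* **Instrument items** are constructed to sum exactly to a per-patient
  target score (discrete normal around the target median, sd 3.5,
  clipped to the score range); the allocation of points across items is
  multivariate-hypergeometric, giving a uniform random feasible vector.

All randomness flows through one seeded `numpy` generator; the written
CSV embeds the configuration as `#` header comments, and identical
seed + configuration gives byte-identical files.

What the simulator does **not** model: correlation between covariates
and survival (age, ECOG and cancer type are decorative margins),
per-patient random censoring (available only as the administrative
horizon), clinician-specific estimation styles, or the discreteness of
real clinician estimates (real ESTs cluster on round numbers; simulated
ESTs are continuous). Passing tests therefore demonstrate the
correctness of the estimators and pipeline under the stated model, not
the empirical accuracy of any clinician population.

## Problem sizes and numerical choices

Simulation-based tests use n = 8 000–50 000 with tolerances of three
Monte-Carlo (or Greenwood) standard errors, and the planted-association
check pools 1 000 resampled 2×2 tables at group sizes 68/68 — sizes at
which the checks are sharp but the full suite stays fast. Degenerate
inputs are first-class: empty or event-free ratio samples are rejected
with diagnostics, zero-cell tables produce NA rather than errors,
all-equal score samples are flagged degenerate, and bands outside the
observed support return zero mass. Exit codes distinguish usage errors
(2) from data/validation failures (1).
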