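# Methods

`trialcea` implements a trial-based cost-effectiveness analysis for a
two-arm randomized comparison (intervention group IG vs control group
CG) with one baseline assessment (T0, 6-month resource-use recall) and
one follow-up (T1, 4-month recall), together with a synthetic trial
generator that stands in for confidential participant-level data.

## Health effects

**Utility index.** Health-related quality of life is measured with the
EQ-5D-5L descriptive system: five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), five ordinal
levels each, hence 3125 describable states. A value set maps the
5-digit profile to a utility index additively: index = intercept +
Σ per-dimension level decrements, with level 1 contributing nothing.
The bundled value set is **synthetic**: it is calibrated only so the
extreme profiles score exactly 1 ("11111") and −0.661 ("55555"), the
range of the German tariff, with decrements growing linearly in level.
Real analyses must load a published coefficient file
(`effects.read_value_set`).

**QALYs.** With two time points, every "linear interpolation" of the
utility trajectory has the same area under the curve, so QALYs over the
horizon h (months) are `(u_T0 + u_T1)/2 * h/12` — the trapezoid. Over
4 months the attainable range is [−0.22, 0.33] after 2-dp rounding. The
EQ-VAS variant divides the 0–100 rating by 100 and applies the same
formula. No discounting is applied at a 4-month horizon. QALYs are
computed from raw per-participant utilities; covariate adjustment
enters later through the regression stage, not by adjusting individual
trajectories.

**Reliable improvement.** Psychological distress is the BSI-18 Global
Severity Index (GSI, 0–72). An individual T0→T1 reduction counts as
reliable improvement when it reaches the Jacobson–Truax reliable-change
threshold `z * SD_ref * sqrt(2) * sqrt(1 − alpha)` with z = 1.96 and
reference constants SD_ref = 7.44, Cronbach alpha = 0.93, giving 5.46
points after 2-dp rounding. The classification uses the *rounded*
printed threshold because the criterion is defined by that value;
`RCIParams.rounding` makes this overridable. The reference mean (4.66)
is carried as metadata only — the threshold formula does not use it.
The comparison `reduction >= threshold` is inclusive.

## Costs

Resource-use quantities per open-ended category are valued with a
unit-cost table (euro per unit at a price year), inflated to the target
year (default 2020) by a consumer price index ratio. Medication is an
ordinary category with unit "pack" — no proprietary drug database is
reconstructed. Informal/formal care hours are valued at a care-worker
gross wage (substitution assumption) via a per-entry `care_wage` flag.

**Indirect costs** follow the human capital approach: absenteeism days
plus presenteeism days — `(1 − w/10) * d` for work-performance rating w
on 0–10 over d days at work — are converted to hours at an 8-hour
workday and valued at the gross wage. Work items are collected at
follow-up only, so indirect costs enter at T1 (an `include_t0_indirect`
switch covers instruments that also ask at baseline).

**Perspectives.** Societal (SP) totals include everything; the payer
perspective (PP) excludes exactly the indirect (work-loss) component.
A per-category `societal_only` flag additionally lets users push chosen
categories (e.g. informal care) out of PP if their convention differs.
The intervention cost is added at T1 for IG participants only, either
as a per-participant amount carried in the reserved `intervention`
resource category or as a scalar override (the "high intervention cost"
sensitivity).

**Winsorization** caps totals above the empirical percentile (default
95th). The cap is the *lower order-statistic* quantile, i.e. a retained
observation; this convention was chosen over interpolated quantiles
because it makes winsorization idempotent (a second pass is a no-op),
which interpolated caps provably are not.

**Missing vs zero.** An unreported quantity is `None`/`NA`, never 0. A
participant with any unreported category in the costed scope gets a
missing total for that window; the complete-case decision is then made
per model, not at costing time.

## Estimation

**Unadjusted comparisons** are one-way linear-model F tests; with two
groups the F statistic is exactly the squared equal-variance two-sample
t statistic (asserted in tests).

**Adjusted contrasts** come from a two-equation seemingly unrelated
regression (SUR) estimated by Zellner two-step feasible GLS:
equation-wise OLS, cross-equation residual covariance Σ (divisor n),
then GLS on the stacked system. One-step (non-iterated) FGLS is the
default, matching common `sureg`-style practice; `iterate=True`
iterates to convergence. The covariate sets follow the trial's
specification — costs: arm, gender identity (two indicators,
trans-masculine reference), age, baseline-window total costs; effects:
arm, gender identity, age, baseline EQ-5D-5L index, baseline GSI. With
identical regressors the FGLS collapses exactly to OLS (the classical
reduction, used as a test oracle). Rank-deficient designs fail with the
collinear columns named.

The binary reliable-improvement outcome enters as a **linear
probability model** so the system stays jointly linear and the arm
coefficient is the adjusted percentage-point difference; known caveats
(predictions outside [0, 1], heteroskedastic errors) apply and
inference leans on the bootstrap.

**Adjusted means** are g-computed: every participant is predicted under
arm = IG and arm = CG and the counterfactual columns are averaged. For
a linear model without arm interactions this equals prediction at
covariate means, and the mean difference equals the arm coefficient —
asserted at run time. Model-based HC0-sandwich SEs are reported, but
all cost-effectiveness uncertainty statements rest on the bootstrap.

**Complete cases, per model.** Rows are dropped only when missing a
variable used by the current equation pair, so the analyzed n varies by
model exactly as in a trial report's n-trail; stage-level row counts
are logged.

## Bootstrap and BCa intervals

The participant is the resampling unit: each of B replicates (default
1000) draws n participants with replacement — keeping each person's
cost and effect paired — and refits the SUR, recording the adjusted
(ΔC, ΔE) pair. Resampling is unstratified by default (an option
stratifies within arm). Replicates that fail to fit are redrawn, up to
10·B attempts, and counted. Draw sets are exactly reproducible from
(seed, B, cohort), ordering included.

BCa intervals use the textbook construction: bias correction
`z0 = Phi^-1(#{draw < point}/B)` (clipped to ±half a count when all
draws fall on one side), acceleration from the jackknife skewness of
leave-one-out estimates, endpoints read from the draws at the adjusted
levels with the linear-interpolation quantile. All draws identical
yields a degenerate [v, v] interval with a warning.

## CEA summaries

The ICER is ΔC/ΔE with quadrant and dominance classification; ΔE = 0
yields a flagged undefined ratio, never a crash. Boundary tie rule:
zero differences count toward the non-negative side (so (0, 0) is NE);
dominance labels require strict signs.

Acceptability curves are computed under two definitions. The default
**net-benefit** curve is the fraction of draws with strictly positive
incremental net monetary benefit `wtp*ΔE − ΔC > 0`; ties count as not
cost-effective. The verbal **ICER-below-threshold** reading is also
emitted: SE-quadrant draws (dominant) always accept, NW never, NE when
the ratio is below the threshold, SW when the ratio is *above* it (a
south-west ratio is a willingness-to-accept, where higher is better).
The two definitions agree exactly on NE-only clouds and can diverge
elsewhere; both are written out so users can see where. Default grids
cover €0–300,000 per QALY (step 1000) and €0–30,000 per reliable
improvement (step 100).

## Synthetic world

The generator emulates the statistical structure of a small telehealth
trial (88 IG / 80 CG):

* **Bounded scores** (utility, EQ-VAS) are censored normals; the
  configured means (0.83/0.87 baseline utility, SD 0.19; small
  follow-up drifts +0.02/−0.03) are targets for the *observed* means,
  so the latent location is solved numerically to compensate for the
  ceiling mass. This reproduces the strong EQ-5D ceiling seen in
  community samples.
* **Costs** per category are zero-inflated lognormal euro amounts
  (baseline category means summing to ≈€3550 over the 6-month window,
  zero masses 0.15–0.9, log-sd 1.0–1.2), stored as quantities =
  euros/unit cost so re-costing the cohort reproduces the draws. The
  follow-up window scales means by 0.248 (shorter recall plus
  waiting-list restraint in both arms), the IG receives a further
  uplift worth €656 in expectation plus a per-participant intervention
  cost ~N(€734, €94) — a configured total follow-up increment of
  €1390. A shared latent Gaussian factor per participant induces a
  cost-effect correlation (default 0.2 — a modeling choice; no joint
  distribution is available to calibrate against).
* **Reliable improvement** is generated as an explicit mixture: with
  the configured arm probability (0.23 IG / 0.09 CG) the GSI reduction
  is threshold + Exponential(4); otherwise the change is Normal(0, 3)
  truncated just below the threshold. The configured probabilities are
  therefore the classification margins by construction, up to a ≈0.5%
  loss from participants whose baseline GSI sits below the threshold.
* **Work items**: ~50% employed; days at work ~N(65, 15), performance
  ~N(9.5, 0.9) clipped to [0, 10], absenteeism zero-inflated lognormal —
  indirect costs average ≈€600–650 per 4 months in both arms.
* **Reproducibility**: one master seed spawns an independent substream
  per (arm, participant index), so growing an arm leaves existing
  participants bit-identical.

What the generator does **not** emulate: item-level BSI-18 responses,
profile-level EQ-5D transitions over time (profile mode draws levels
i.i.d. per dimension), real national CPI series or unit-cost
catalogues, informative missingness, or recall bias. A green test on
synthetic data therefore establishes the *statistical machinery* —
estimator identities, calibration, determinism — not the clinical
conclusions of any particular trial.

## Numerical choices and degenerate inputs

* FGLS solves the stacked normal equations directly (2×2 Σ inverse);
  Σ is checked symmetric PSD on every fit.
* Floats in cohort CSVs are written with `repr` (shortest exact
  round-trip), making write∘read the identity and reruns byte-stable.
* `z0` clipping at ±Phi^-1(1/2B) keeps BCa endpoints finite when the
  point estimate falls outside the draw range.
* Per-arm sizes below the parameter count, empty winsorization input,
  zero within-group variance in the F test, unknown cost categories,
  and subgroups smaller than the design all raise named errors rather
  than propagating NaNs.

## Known limitations

* The LPM effect equation can predict adjusted proportions outside
  [0, 1] far from the data; checked on defaults but not constrained.
* BCa coverage on heavy-tailed zero-inflated costs is mildly
  anti-conservative at small n (measured ≈0.92 for nominal 0.95 at
  n=50/arm under the null world) — inherent to bootstrapping skewed
  means, not a defect of the construction.
* Multiple imputation is out of scope; the package follows the
  complete-case route appropriate when missingness is negligible and
  completely at random.
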