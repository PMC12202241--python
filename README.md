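# trialcea

Trial-based cost-effectiveness analysis in Python: from per-participant
questionnaire and resource-use records to covariate-adjusted
incremental cost-effectiveness ratios (ICERs), cost-effectiveness
planes, and acceptability curves — plus a seeded synthetic two-arm
trial generator so every stage is testable when the underlying trial
data cannot be shared.

It is written for health economists running economic evaluations
alongside small randomized trials: two arms (intervention IG vs control
CG), a baseline assessment with a 6-month resource-use recall, and one
follow-up at 4 months.

## What it computes

* **Health effects** — EQ-5D-5L utility indices from 5-digit profiles
  through an additive value set; QALYs as the area under the linearly
  interpolated utility curve, `(u_T0+u_T1)/2 × h/12`; EQ-VAS QALYs; and
  reliable improvement on the BSI-18 GSI via the Jacobson–Truax
  reliable change index, `z·SD_ref·√2·√(1−α)` (= 5.46 points with the
  reference constants SD 7.44, α = .93, z = 1.96).
* **Costs** — unit-cost valuation of open-ended resource-use
  categories with CPI inflation to a target price year; informal care
  at a substitution wage; human-capital indirect costs from
  absenteeism plus presenteeism `(1−w/10)·d` at an 8-hour workday;
  societal (SP) vs payer (PP) perspectives; intervention costs added to
  IG follow-up totals; 95th-percentile winsorization.
* **Estimation** — unadjusted F tests; a two-equation seemingly
  unrelated regression (Zellner two-step FGLS) giving adjusted IG−CG
  differences in total costs and one effect measure, ΔC and ΔE.
* **Uncertainty** — participant-level nonparametric bootstrap of the
  whole SUR (default B = 1000), bias-corrected and accelerated (BCa)
  intervals, the cost-effectiveness plane, and acceptability curves
  (CEACs) from the net-benefit approach: the probability that
  `λ·ΔE − ΔC > 0` as a function of willingness-to-pay λ.

The headline statistic is the adjusted ICER = ΔC/ΔE.

## Worked example

```python
import trialcea as t
from trialcea.cea import ceac

cohort = t.generate_cohort(t.GeneratorConfig(seed=7))   # 88 IG / 80 CG
uc, vs = t.default_unit_cost_table(), t.bundled_value_set()
res = t.run_analysis(cohort, uc, vs, t.AnalysisConfig(B=1000, seed=7))

print(res.manifest["n_sur"])                 # 168
print(round(res.contrast_cost.difference))   # 1117   (adjusted delta-C, euros)
print(round(res.contrast_effect.difference, 4))  # 0.0084 (adjusted delta-QALY)
print(round(res.icer_result.icer))           # 133612 (euros per QALY, NE quadrant)
print(res.plane["NE"])                       # 0.999  (draws in the NE quadrant)
for w in (0, 50_000, 150_000, 300_000):
    print(w, float(ceac(res.draws, [w]).probability[0]))
# 0 0.0   50000 0.0   150000 0.62   300000 0.96
```

Reading: in this synthetic replicate the intervention arm cost €1117
more over 4 months (bootstrap cloud almost entirely in the
costlier-and-more-effective quadrant) and gained 0.0084 QALYs, an ICER
of ≈€134,000 per QALY; the intervention only becomes more likely
cost-effective than not at a willingness-to-pay beyond ≈€135,000 per
QALY. Single-trial-sized replicates scatter widely around the
generator's configured truth (ΔC = €1390) — that sampling noise is the
point of the bootstrap machinery.

The same pipeline runs from the shell:

```sh
trialcea synth --seed 7 --out cohort.csv
trialcea run --cohort cohort.csv --seed 7 --out results/
trialcea sensitivity --cohort cohort.csv --config variants.yaml --out sens.csv
```

`run` writes unadjusted (arm means, F tests) and adjusted summary
tables, the (ΔC, ΔE) draw set with a JSON sidecar, CEAC and plane CSVs,
a headline JSON, and a manifest that reproduces the run byte-for-byte.
Sensitivity variants cover winsorized costs, high intervention costs,
mental-health-only cost scope, the payer perspective, per-protocol and
complete-case populations, and gender-identity subgroups.

File formats (cohort, unit-cost, and value-set CSVs) are documented in
`docs/cohort_schema.md`; the statistical methods, the synthetic world's
assumptions, and its limitations in `docs/methods.md`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the package's own functions, the exactly checkable
worked values — the Jacobson–Truax reliable-change threshold from the
reference constants and the minimum/maximum QALYs accruable over the
4-month horizon at the utility-index bounds — and writes them as JSON.
It also executes a seeded end-to-end synthetic analysis as a smoke
check of the full pipeline.
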