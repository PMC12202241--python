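# Cohort CSV column dictionary

First line: a comment `# trialcea-cohort schema_version=1
recall_months_t0=6 recall_months_t1=4`. Second line: the header. One
data row per participant. Empty numeric cells mean "not reported"
(never zero). In resource-use columns, `NA` means the category was
asked but the quantity is missing, while an empty cell means the
category was not collected for this participant.

| column | type | range / values | notes |
|---|---|---|---|
| participant_id | string | unique | opaque identifier |
| arm | enum | `IG`, `CG` | intervention / control |
| age_years | float | ≥ 0 | |
| gender_identity | enum | `trans_masculine`, `trans_feminine`, `nonbinary` | |
| eq5d_profile_t0, eq5d_profile_t1 | string | 5 digits, each 1–5 | optional when the index is supplied |
| eq5d_index_t0, eq5d_index_t1 | float | [−0.661, 1] | utility index |
| eq_vas_t0, eq_vas_t1 | float | [0, 100] | visual analogue rating |
| gsi_t0, gsi_t1 | float | [0, 72] | BSI-18 Global Severity Index |
| work_days_absent_t1 | float | ≥ 0 | absenteeism, follow-up recall |
| work_days_present_t1 | float | ≥ 0 | days at work (d) |
| work_performance_t1 | float | [0, 10] | overall work performance (w) |
| analysis_flags | set | `;`-joined subset of `intention_to_treat`, `analysis_population`, `per_protocol` | population membership |
| `ru_t0:<category>` | float | ≥ 0 or `NA` | baseline-window quantity in the unit of the unit-cost table |
| `ru_t1:<category>` | float | ≥ 0 or `NA` | follow-up-window quantity; `ru_t1:intervention` carries per-participant intervention euros (unit cost 1) |

# Unit-cost CSV

Columns: `category, unit, euro_per_unit, price_year`, optional
`care_wage` (0/1: value hours at the care wage instead of
euro_per_unit) and `societal_only` (0/1: exclude from payer-perspective
totals). CPI series, target year, wages and the mental-health category
subset are supplied programmatically (`costing.read_unit_cost_table`
keyword arguments).

# Value-set CSV

Columns: `dimension, level, decrement` with dimensions `MO, SC, UA,
PD, AD` and levels 2–5 (level-1 decrements are identically zero), plus
one `INTERCEPT` row whose `decrement` column holds the intercept (must
be 1.0). Decrements are ≤ 0 and non-increasing in level.
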