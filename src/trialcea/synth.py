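"""Seeded synthetic two-arm trial generator.

Emulates the statistical structure of a small eHealth trial with a
6-month baseline recall window and a 4-month follow-up: bounded EQ-5D-5L
utilities with a strong ceiling, right-skewed zero-inflated category
costs, a mixture-generated reliable-improvement margin on the BSI-18
GSI, and a fixed per-participant intervention cost in the IG only.

Category costs are drawn as euro amounts from zero-inflated lognormal
distributions and stored as quantities (euros divided by the unit cost),
so costing the generated cohort with the same unit-cost table reproduces
the drawn euros exactly.  A shared latent Gaussian factor per
participant induces a configurable cost-effect correlation.

Reproducibility: a single master seed feeds one spawned substream per
(arm, participant-index) pair, so enlarging an arm leaves the
already-generated participants unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .costing import INTERVENTION_CATEGORY, UnitCostTable, default_unit_cost_table
from .effects import RCIParams, bundled_value_set, rci_threshold, score_profile
from .trial_io import UTILITY_FLOOR, CohortTable, ParticipantRecord

__all__ = [
    "CostCategoryParams",
    "GeneratorConfig",
    "generate_cohort",
    "inject_missingness",
]


@dataclass(frozen=True)
class CostCategoryParams:
    """Zero-inflated lognormal euros for one category (baseline window)."""

    zero_prob: float
    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.zero_prob <= 1.0):
            raise ValueError("zero_prob must lie in [0, 1]")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    @classmethod
    def from_mean(cls, mean: float, zero_prob: float, log_sd: float) -> "CostCategoryParams":
        """Parameters hitting an unconditional mean euro amount."""
        if mean <= 0:
            raise ValueError("mean must be positive")
        log_mean = math.log(mean / (1.0 - zero_prob)) - log_sd**2 / 2.0
        return cls(zero_prob, log_mean, log_sd)

    @property
    def mean(self) -> float:
        return (1.0 - self.zero_prob) * math.exp(self.log_mean + self.log_sd**2 / 2.0)


def _default_cost_params() -> dict[str, CostCategoryParams]:
    # 6-month baseline means (euros) summing to 3550, with zero masses and
    # log-scale spreads chosen so the per-arm SE of the total at n~80 lands
    # near 700 euros — many zeros, heavy right tail.
    targets = {
        "inpatient_care": (1100.0, 0.85, 1.2),
        "outpatient_physician": (600.0, 0.15, 1.0),
        "outpatient_nonphysician": (150.0, 0.60, 1.2),
        "medical_aids": (60.0, 0.70, 1.0),
        "medical_counseling": (120.0, 0.70, 1.0),
        "psychotherapy": (250.0, 0.75, 1.0),
        "transportation": (60.0, 0.30, 1.0),
        "medication": (160.0, 0.40, 1.2),
        "nursing_care": (300.0, 0.90, 1.2),
        "informal_care": (750.0, 0.70, 1.2),
    }
    return {
        cat: CostCategoryParams.from_mean(mean, p, sd) for cat, (mean, p, sd) in targets.items()
    }


@dataclass
class GeneratorConfig:
    """All knobs of the stated synthetic world, with trial-like defaults."""

    n_ig: int = 88
    n_cg: int = 80
    seed: int = 0

    # EQ-5D-5L index: baseline ceiling-heavy normals, small arm-specific drift
    utility_baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"IG": 0.83, "CG": 0.87}
    )
    utility_sd: float = 0.19
    utility_effect_t1: dict[str, float] = field(
        default_factory=lambda: {"IG": 0.02, "CG": -0.03}
    )
    utility_change_sd: float = 0.12

    # EQ-VAS (0-100)
    vas_baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"IG": 68.52, "CG": 72.73}
    )
    vas_sd: float = 20.6
    vas_effect_t1: dict[str, float] = field(default_factory=lambda: {"IG": 1.55, "CG": -2.28})
    vas_change_sd: float = 10.0

    # BSI-18 GSI and the reliable-improvement mixture
    gsi_baseline_mean: float = 30.0
    gsi_sd: float = 12.0
    reliable_improvement_prob: dict[str, float] = field(
        default_factory=lambda: {"IG": 0.23, "CG": 0.09}
    )
    responder_excess_scale: float = 4.0
    nonresponder_change_sd: float = 3.0
    rci: RCIParams = field(default_factory=RCIParams)

    # Costs
    cost_category_params: dict[str, CostCategoryParams] = field(
        default_factory=_default_cost_params
    )
    followup_scale: float = 0.248  # 4-month window + waiting-list restraint
    ig_followup_cost_uplift: float = 656.0  # extra IG service use at T1, euros
    cost_effect_correlation: float = 0.2
    intervention_cost_mean: float = 734.0
    intervention_cost_sd: float = 94.0  # SE 10 at n=88 -> SD ~ 10 * sqrt(88)

    # Covariates
    gender_identity_probs: tuple[float, float, float] = (73 / 168, 57 / 168, 38 / 168)
    age_mean: float = 26.8
    age_sd: float = 10.0

    # Work (follow-up window): ~half employed, high performance ratings
    employment_prob: float = 0.5
    days_at_work_mean: float = 65.0
    days_at_work_sd: float = 15.0
    absent_zero_prob: float = 0.6
    absent_mean_days: float = 2.5
    absent_log_sd: float = 0.8
    performance_mean: float = 9.5
    performance_sd: float = 0.9

    per_protocol_dropout: float = 7 / 168
    profile_mode: bool = False

    def validate(self) -> None:
        if self.n_ig <= 0 or self.n_cg <= 0:
            raise ValueError("arm sizes must be positive")
        if abs(sum(self.gender_identity_probs) - 1.0) > 1e-9:
            raise ValueError("gender_identity_probs must sum to 1")
        for p in self.gender_identity_probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError("gender_identity_probs must lie in [0, 1]")
        for arm in ("IG", "CG"):
            if not (0.0 <= self.reliable_improvement_prob[arm] <= 1.0):
                raise ValueError("reliable_improvement_prob must lie in [0, 1]")
        for sd in (self.utility_sd, self.gsi_sd, self.vas_sd, self.age_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be positive")
        if not (-1.0 < self.cost_effect_correlation < 1.0):
            raise ValueError("cost_effect_correlation must lie in (-1, 1)")
        if self.followup_scale <= 0:
            raise ValueError("followup_scale must be positive")


_GENDER_LEVELS = ("trans_masculine", "trans_feminine", "nonbinary")
_PROFILE_LEVEL_PROBS = (0.55, 0.25, 0.12, 0.06, 0.02)


def _clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))


def _censored_mean(m: float, sd: float, lo: float, hi: float) -> float:
    """Mean of clip(N(m, sd), lo, hi)."""
    a = (lo - m) / sd
    b = (hi - m) / sd
    return (
        lo * stats.norm.cdf(a)
        + hi * stats.norm.sf(b)
        + m * (stats.norm.cdf(b) - stats.norm.cdf(a))
        - sd * (stats.norm.pdf(b) - stats.norm.pdf(a))
    )


def _latent_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal mean whose clipped mean equals the target.

    Bounded scores (utilities in [floor, 1], EQ-VAS in [0, 100]) are
    generated as censored normals; the configured means are the target
    *observed* means, so the latent location compensates for the mass
    piled onto the bounds.
    """
    if not (lo < target < hi):
        raise ValueError(f"target mean {target} must lie strictly inside ({lo}, {hi})")
    return float(
        optimize.brentq(
            lambda m: _censored_mean(m, sd, lo, hi) - target, lo - 10 * sd, hi + 10 * sd
        )
    )


def generate_cohort(config: GeneratorConfig, uc: UnitCostTable | None = None) -> CohortTable:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    if uc is None:
        uc = default_unit_cost_table()
    for cat in config.cost_category_params:
        if cat not in uc.entries:
            raise KeyError(f"cost category {cat!r} missing from the unit-cost table")

    threshold = rci_threshold(config.rci)
    rho = config.cost_effect_correlation
    vs = bundled_value_set() if config.profile_mode else None

    # Latent locations so the *observed* (censored) means hit the targets
    u_sd1 = math.sqrt(config.utility_sd**2 + config.utility_change_sd**2)
    v_sd1 = math.sqrt(config.vas_sd**2 + config.vas_change_sd**2)
    u_lat0, u_eff, v_lat0, v_eff = {}, {}, {}, {}
    for arm in ("IG", "CG"):
        u_lat0[arm] = _latent_mean(
            config.utility_baseline_mean[arm], config.utility_sd, UTILITY_FLOOR, 1.0
        )
        u_eff[arm] = (
            _latent_mean(
                config.utility_baseline_mean[arm] + config.utility_effect_t1[arm],
                u_sd1,
                UTILITY_FLOOR,
                1.0,
            )
            - u_lat0[arm]
        )
        v_lat0[arm] = _latent_mean(config.vas_baseline_mean[arm], config.vas_sd, 0.0, 100.0)
        v_eff[arm] = (
            _latent_mean(
                config.vas_baseline_mean[arm] + config.vas_effect_t1[arm], v_sd1, 0.0, 100.0
            )
            - v_lat0[arm]
        )

    records: list[ParticipantRecord] = []
    for arm_idx, (arm, n) in enumerate((("IG", config.n_ig), ("CG", config.n_cg))):
        for i in range(n):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(arm_idx, i))
            rng = np.random.default_rng(ss)
            pid = f"{arm}{i + 1:04d}"

            gender = _GENDER_LEVELS[
                int(rng.choice(3, p=np.asarray(config.gender_identity_probs)))
            ]
            age = _clip(rng.normal(config.age_mean, config.age_sd), 18.0, 90.0)
            z = rng.standard_normal()  # shared latent cost-effect factor

            # EQ-5D-5L index (ceiling effects via clipping)
            profile_t0 = profile_t1 = None
            if config.profile_mode:
                lv0 = rng.choice(5, size=5, p=_PROFILE_LEVEL_PROBS) + 1
                lv1 = rng.choice(5, size=5, p=_PROFILE_LEVEL_PROBS) + 1
                profile_t0 = "".join(str(int(v)) for v in lv0)
                profile_t1 = "".join(str(int(v)) for v in lv1)
                u0 = score_profile(profile_t0, vs)
                u1 = score_profile(profile_t1, vs)
            else:
                u0_lat = rng.normal(u_lat0[arm], config.utility_sd)
                u0 = _clip(u0_lat, UTILITY_FLOOR, 1.0)
                eps = rho * z + math.sqrt(1.0 - rho**2) * rng.standard_normal()
                u1 = _clip(
                    u0_lat + u_eff[arm] + config.utility_change_sd * eps, UTILITY_FLOOR, 1.0
                )

            v0_lat = rng.normal(v_lat0[arm], config.vas_sd)
            v0 = _clip(v0_lat, 0.0, 100.0)
            v1 = _clip(
                v0_lat + v_eff[arm] + rng.normal(0.0, config.vas_change_sd), 0.0, 100.0
            )

            # GSI mixture: responders cross the reliable-change threshold,
            # non-responders are truncated just below it so the configured
            # arm probabilities are the classification margins.
            g0 = _clip(rng.normal(config.gsi_baseline_mean, config.gsi_sd), 0.0, 72.0)
            if rng.random() < config.reliable_improvement_prob[arm]:
                reduction = threshold + rng.exponential(config.responder_excess_scale)
            else:
                reduction = min(
                    rng.normal(0.0, config.nonresponder_change_sd), threshold - 0.01
                )
            g1 = _clip(g0 - reduction, 0.0, 72.0)

            # Category costs: zero-inflated lognormal euros -> quantities
            uplift = 1.0
            if arm == "IG" and config.ig_followup_cost_uplift > 0:
                base_t1_total = sum(p.mean for p in config.cost_category_params.values())
                uplift = 1.0 + config.ig_followup_cost_uplift / (
                    base_t1_total * config.followup_scale
                )
            ru0: dict[str, float | None] = {}
            ru1: dict[str, float | None] = {}
            for cat, params in config.cost_category_params.items():
                unit = uc.unit_cost(cat)
                for window, store in (("T0", ru0), ("T1", ru1)):
                    if rng.random() < params.zero_prob:
                        store[cat] = 0.0
                        continue
                    xi = rho * z + math.sqrt(1.0 - rho**2) * rng.standard_normal()
                    mu = params.log_mean
                    if window == "T1":
                        mu += math.log(config.followup_scale)
                        if arm == "IG":
                            mu += math.log(uplift)
                    euros = math.exp(mu + params.log_sd * xi)
                    store[cat] = euros / unit if unit > 0 else euros

            if arm == "IG":
                ru1[INTERVENTION_CATEGORY] = max(
                    rng.normal(config.intervention_cost_mean, config.intervention_cost_sd),
                    0.0,
                )

            # Work items (follow-up recall only)
            if rng.random() < config.employment_prob:
                days = max(rng.normal(config.days_at_work_mean, config.days_at_work_sd), 0.0)
                perf = _clip(rng.normal(config.performance_mean, config.performance_sd), 0.0, 10.0)
                if rng.random() < config.absent_zero_prob:
                    absent = 0.0
                else:
                    mu_a = math.log(config.absent_mean_days) - config.absent_log_sd**2 / 2.0
                    absent = math.exp(rng.normal(mu_a, config.absent_log_sd))
            else:
                days, perf, absent = 0.0, 10.0, 0.0

            flags = {"intention_to_treat", "analysis_population"}
            if rng.random() >= config.per_protocol_dropout:
                flags.add("per_protocol")

            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    arm=arm,
                    age_years=age,
                    gender_identity=gender,
                    eq5d_profile_t0=profile_t0,
                    eq5d_profile_t1=profile_t1,
                    eq5d_index_t0=u0,
                    eq5d_index_t1=u1,
                    eq_vas_t0=v0,
                    eq_vas_t1=v1,
                    gsi_t0=g0,
                    gsi_t1=g1,
                    resource_use_t0=ru0,
                    resource_use_t1=ru1,
                    work_days_absent_t1=absent,
                    work_days_present_t1=days,
                    work_performance_t1=perf,
                    analysis_flags=frozenset(flags),
                )
            )

    cohort = CohortTable(records, recall_months_t0=6.0, recall_months_t1=4.0)
    cohort.validate()
    return cohort


#: fields maskable by MCAR missingness (never arm or participant_id)
_MASKABLE = (
    "age_years",
    "gender_identity",
    "eq5d_index_t0",
    "eq5d_index_t1",
    "eq_vas_t0",
    "eq_vas_t1",
    "gsi_t0",
    "gsi_t1",
    "work_days_absent_t1",
    "work_days_present_t1",
    "work_performance_t1",
)


def inject_missingness(cohort: CohortTable, rate: float, seed: int) -> CohortTable:
    """Mask fields missing-completely-at-random at a per-field rate.

    Resource-use categories (except the reserved intervention amount,
    which is program-side data) are masked as well; arm and participant
    id never are.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[ParticipantRecord] = []
    for rec in cohort.records:
        changes: dict = {}
        for name in _MASKABLE:
            if getattr(rec, name) is not None and rng.random() < rate:
                changes[name] = None
        for attr in ("resource_use_t0", "resource_use_t1"):
            ru = getattr(rec, attr)
            masked = {
                cat: (
                    None
                    if cat != INTERVENTION_CATEGORY and qty is not None and rng.random() < rate
                    else qty
                )
                for cat, qty in ru.items()
            }
            changes[attr] = masked
        out.append(replace(rec, **changes))
    return CohortTable(out, cohort.recall_months_t0, cohort.recall_months_t1)
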