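"""End-to-end orchestration: effects -> costing -> SUR -> bootstrap -> CEA.

One :class:`AnalysisConfig` drives a full run for a chosen perspective,
effect measure, population, optional gender-identity subgroup, and the
sensitivity variants (winsorized costs, high intervention costs, mental
health related costs only).  Internal computation is full precision;
rounding to whole euros / stated decimals happens only when presenting.

Complete-case filtering is per model: a participant is dropped only when
missing a variable used by the current equation pair, so the analyzed n
varies with the model exactly as in a trial report's n-trail.  Stage-level
row counts are logged so attrition is auditable from the log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import CEACCurve, ICERResult, ceac, default_wtp_grid, icer, plane_summary
from .costing import UnitCostTable, cost_participant, winsorize_totals
from .effects import RCIParams, ValueSet, qaly_auc, rci_threshold, reliable_improvement, score_profile, vas_qaly
from .resampling import DrawSet, bootstrap_contrasts
from .sur import (
    AdjustedContrast,
    SURSpec,
    UnadjustedComparison,
    adjusted_contrast,
    fit_sur,
    unadjusted_comparison,
)
from .trial_io import CohortTable

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "build_analysis_table",
    "run_analysis",
    "run_sensitivity_suite",
]

log = logging.getLogger(__name__)

POPULATIONS = ("analysis", "per_protocol", "complete_case")
COST_SCOPES = ("all", "mental_health_only")
INTERVENTION_MODES = ("standard", "high")


@dataclass
class AnalysisConfig:
    """One analysis run: population, perspective, effect, and variants."""

    population: str = "analysis"
    perspective: str = "SP"
    effect_measure: str = "QALY_EQ5D"
    subgroup: str | None = None  # gender-identity filter
    winsorize: float | None = None  # percentile, e.g. 95
    cost_scope: str = "all"
    intervention_cost_mode: str = "standard"
    intervention_cost_high: float = 1100.0  # euros, wage-based revaluation
    B: int = 1000
    seed: int = 0
    wtp_grid: np.ndarray | None = None
    alpha: float = 0.05
    rci: RCIParams = field(default_factory=RCIParams)
    stratify_bootstrap: bool = False

    def validate(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")
        if self.perspective not in ("SP", "PP"):
            raise ValueError("perspective must be SP or PP")
        if self.cost_scope not in COST_SCOPES:
            raise ValueError(f"cost_scope must be one of {COST_SCOPES}")
        if self.intervention_cost_mode not in INTERVENTION_MODES:
            raise ValueError(f"intervention_cost_mode must be one of {INTERVENTION_MODES}")
        if self.B > 0 and self.seed is None:
            raise ValueError("seed is mandatory when B > 0")
        if self.winsorize is not None and not (0.0 < self.winsorize < 100.0):
            raise ValueError("winsorize percentile must lie strictly between 0 and 100")
        SURSpec(effect_name=self.effect_measure)  # validates the effect name


@dataclass
class AnalysisResult:
    table: pd.DataFrame
    unadjusted: pd.DataFrame
    contrast_cost: AdjustedContrast
    contrast_effect: AdjustedContrast
    draws: DrawSet | None
    icer_result: ICERResult
    plane: dict[str, float] | None
    ceac_curves: dict[str, CEACCurve]
    manifest: dict


def _record_total(rec, window, uc, perspective, categories, intervention_cost):
    """Total euros, or NaN when any costed category quantity is unreported."""
    ru = rec.resource_use_t0 if window == "T0" else rec.resource_use_t1
    for cat, qty in ru.items():
        if qty is None and (categories is None or cat in categories):
            return float("nan")
    bd = cost_participant(
        rec,
        window,
        uc,
        perspective=perspective,
        categories=categories,
        intervention_cost=intervention_cost,
    )
    return bd.total


def build_analysis_table(
    cohort: CohortTable,
    uc: UnitCostTable,
    vs: ValueSet,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Per-participant analysis variables for the configured run.

    EQ-5D-5L indices are taken as supplied, or scored from the 5-digit
    profile through the value set when only the profile is present.
    """
    cfg.validate()
    threshold = rci_threshold(cfg.rci)
    horizon = cohort.recall_months_t1
    categories = None
    if cfg.cost_scope == "mental_health_only":
        categories = uc.mental_health_categories
    interv_override = (
        cfg.intervention_cost_high if cfg.intervention_cost_mode == "high" else None
    )

    flag = "per_protocol" if cfg.population == "per_protocol" else "analysis_population"
    records = [r for r in cohort.records if flag in r.analysis_flags]
    log.info("population filter %r: %d of %d participants", cfg.population, len(records), len(cohort))
    if cfg.subgroup is not None:
        records = [r for r in records if r.gender_identity == cfg.subgroup]
        log.info("subgroup %r: %d participants", cfg.subgroup, len(records))

    rows = []
    for rec in records:
        u0, u1 = rec.eq5d_index_t0, rec.eq5d_index_t1
        if u0 is None and rec.eq5d_profile_t0 is not None:
            u0 = score_profile(rec.eq5d_profile_t0, vs)
        if u1 is None and rec.eq5d_profile_t1 is not None:
            u1 = score_profile(rec.eq5d_profile_t1, vs)
        qaly = qaly_auc(u0, u1, horizon) if u0 is not None and u1 is not None else np.nan
        vq = (
            vas_qaly(rec.eq_vas_t0, rec.eq_vas_t1, horizon)
            if rec.eq_vas_t0 is not None and rec.eq_vas_t1 is not None
            else np.nan
        )
        ri = (
            float(reliable_improvement(rec.gsi_t0, rec.gsi_t1, threshold))
            if rec.gsi_t0 is not None and rec.gsi_t1 is not None
            else np.nan
        )
        rows.append(
            {
                "participant_id": rec.participant_id,
                "arm_ig": 1.0 if rec.arm == "IG" else 0.0,
                "age_years": np.nan if rec.age_years is None else rec.age_years,
                "gi_trans_feminine": (
                    np.nan
                    if rec.gender_identity is None
                    else float(rec.gender_identity == "trans_feminine")
                ),
                "gi_nonbinary": (
                    np.nan
                    if rec.gender_identity is None
                    else float(rec.gender_identity == "nonbinary")
                ),
                "eq5d_index_t0": np.nan if u0 is None else u0,
                "eq5d_index_t1": np.nan if u1 is None else u1,
                "gsi_t0": np.nan if rec.gsi_t0 is None else rec.gsi_t0,
                "baseline_cost": _record_total(rec, "T0", uc, cfg.perspective, categories, None),
                "cost_t1": _record_total(
                    rec, "T1", uc, cfg.perspective, categories, interv_override
                ),
                "intervention_cost": (
                    rec.resource_use_t1.get("intervention") or 0.0
                    if interv_override is None
                    else (interv_override if rec.arm == "IG" else 0.0)
                ),
                "qaly_eq5d": qaly,
                "qaly_vas": vq,
                "reliable_improvement": ri,
            }
        )
    table = pd.DataFrame(rows).set_index("participant_id")

    if cfg.winsorize is not None and len(table):
        for col in ("baseline_cost", "cost_t1"):
            vals = table[col].to_numpy(float)
            ok = np.isfinite(vals)
            if ok.any():
                vals[ok] = winsorize_totals(vals[ok], cfg.winsorize)
                table[col] = vals

    if cfg.population == "complete_case":
        spec = SURSpec(effect_name=cfg.effect_measure)
        used = sorted(
            {spec.cost_outcome, spec.effect_outcome}
            | set(spec.cost_covariates)
            | set(spec.effect_covariates)
        )
        table = table.dropna(subset=used)
    log.info("analysis table: %d rows", len(table))
    return table


def _unadjusted_rows(table: pd.DataFrame) -> pd.DataFrame:
    out = []
    ig = table[table["arm_ig"] == 1.0]
    cg = table[table["arm_ig"] == 0.0]
    for label, col in (
        ("intervention_cost", "intervention_cost"),
        ("total_cost_t0", "baseline_cost"),
        ("total_cost_t1", "cost_t1"),
        ("eq5d_index_t0", "eq5d_index_t0"),
        ("eq5d_index_t1", "eq5d_index_t1"),
        ("qaly_eq5d", "qaly_eq5d"),
        ("qaly_vas", "qaly_vas"),
        ("reliable_improvement", "reliable_improvement"),
    ):
        a = ig[col].dropna()
        b = cg[col].dropna()
        try:
            cmp: UnadjustedComparison | None = unadjusted_comparison(a, b)
        except Exception:
            cmp = None
        out.append(
            {
                "measure": label,
                "n_ig": len(a),
                "n_cg": len(b),
                "mean_ig": a.mean() if len(a) else np.nan,
                "mean_cg": b.mean() if len(b) else np.nan,
                "se_ig": a.sem() if len(a) > 1 else np.nan,
                "se_cg": b.sem() if len(b) > 1 else np.nan,
                "difference": (a.mean() - b.mean()) if len(a) and len(b) else np.nan,
                "f_stat": cmp.f_stat if cmp else np.nan,
                "p_value": cmp.p_value if cmp else np.nan,
            }
        )
    return pd.DataFrame(out)


def run_analysis(
    cohort: CohortTable,
    uc: UnitCostTable,
    vs: ValueSet,
    cfg: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> AnalysisResult:
    """Execute the full chain and (optionally) write all artifacts."""
    cfg.validate()
    table = build_analysis_table(cohort, uc, vs, cfg)
    spec = SURSpec(effect_name=cfg.effect_measure)

    fit = fit_sur(table, spec)
    log.info("SUR fit on %d complete cases", fit.n_used)
    c_cost, c_eff = adjusted_contrast(fit, table)
    point_icer = icer(c_cost.difference, c_eff.difference)

    draws = None
    plane = None
    curves: dict[str, CEACCurve] = {}
    if cfg.B > 0:
        draws = bootstrap_contrasts(
            table, spec, B=cfg.B, seed=cfg.seed, stratify_by_arm=cfg.stratify_bootstrap
        )
        plane = plane_summary(draws)
        grid = cfg.wtp_grid if cfg.wtp_grid is not None else default_wtp_grid(cfg.effect_measure)
        for definition in ("net_benefit", "icer_below_wtp"):
            curves[definition] = ceac(draws, grid, definition)

    manifest = {
        "package": "trialcea",
        "version": __version__,
        "config": _config_dict(cfg),
        "n_cohort": len(cohort),
        "n_table": int(len(table)),
        "n_sur": int(fit.n_used),
        "seed": cfg.seed,
    }
    result = AnalysisResult(
        table=table,
        unadjusted=_unadjusted_rows(table),
        contrast_cost=c_cost,
        contrast_effect=c_eff,
        draws=draws,
        icer_result=point_icer,
        plane=plane,
        ceac_curves=curves,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _config_dict(cfg: AnalysisConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("wtp_grid") is not None:
        d["wtp_grid"] = [float(x) for x in np.asarray(d["wtp_grid"]).ravel()]
    return d


def _write_artifacts(result: AnalysisResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.unadjusted.to_csv(out_dir / "unadjusted.csv", index=False)
    adjusted = pd.DataFrame(
        [dataclasses.asdict(result.contrast_cost), dataclasses.asdict(result.contrast_effect)]
    )
    adjusted.to_csv(out_dir / "adjusted.csv", index=False)
    headline = {
        "delta_cost": result.contrast_cost.difference,
        "delta_effect": result.contrast_effect.difference,
        "icer": result.icer_result.icer,
        "quadrant": result.icer_result.quadrant,
        "dominance": result.icer_result.dominance,
        "plane_fractions": result.plane,
    }
    (out_dir / "headline.json").write_text(json.dumps(headline, indent=2, sort_keys=True) + "\n")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    if result.draws is not None:
        result.draws.to_frame().to_csv(out_dir / "draws.csv", index=False)
        sidecar = {
            "B": result.draws.B,
            "seed": result.draws.seed,
            "n": result.draws.n,
            "n_retries": result.draws.n_retries,
            "stratified": result.draws.stratified,
            "point_estimate": list(result.draws.point_estimate),
        }
        (out_dir / "draws.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
        frames = []
        for definition, curve in result.ceac_curves.items():
            frames.append(
                pd.DataFrame(
                    {
                        "wtp": curve.wtp_grid,
                        "probability": curve.probability,
                        "definition": definition,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(out_dir / "ceac.csv", index=False)
        plane_df = result.draws.to_frame()
        plane_df["quadrant"] = [
            icer(c, e).quadrant for c, e in zip(plane_df["delta_cost"], plane_df["delta_effect"])
        ]
        plane_df.to_csv(out_dir / "plane.csv", index=False)


def run_sensitivity_suite(
    cohort: CohortTable,
    uc: UnitCostTable,
    vs: ValueSet,
    base_cfg: AnalysisConfig,
    variants: list[dict],
) -> pd.DataFrame:
    """Base run plus one headline row (dC, dE, ICER) per variant override.

    Variant errors are captured per row rather than aborting the suite.
    """
    rows = []
    specs: list[tuple[str, dict]] = [("base", {})] + [
        (ov.get("label", f"variant_{i + 1}"), {k: v for k, v in ov.items() if k != "label"})
        for i, ov in enumerate(variants)
    ]
    for label, overrides in specs:
        cfg = dataclasses.replace(base_cfg, **overrides)
        try:
            res = run_analysis(cohort, uc, vs, cfg)
            rows.append(
                {
                    "label": label,
                    "n": res.manifest["n_sur"],
                    "delta_cost": res.contrast_cost.difference,
                    "delta_effect": res.contrast_effect.difference,
                    "icer": res.icer_result.icer,
                    "error": "",
                }
            )
        except Exception as exc:  # propagate per variant, keep the suite going
            rows.append(
                {
                    "label": label,
                    "n": np.nan,
                    "delta_cost": np.nan,
                    "delta_effect": np.nan,
                    "icer": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
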