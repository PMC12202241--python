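"""Nonparametric bootstrap of the SUR pipeline and BCa intervals.

The unit of resampling is the participant: each replicate draws n rows
with replacement (pairing every participant's cost with their effect),
refits the two-equation system, and records the adjusted (delta-cost,
delta-effect) pair.  Replicates whose resample cannot be fitted (e.g. a
collinear design) are redrawn with fresh resamples up to a bounded retry
budget and counted — silently dropping them would bias acceptability
denominators.

Confidence intervals follow the standard bias-corrected and accelerated
(BCa) construction: the bias correction z0 from the fraction of draws
below the full-sample point estimate, the acceleration a from the
skewness of jackknife (leave-one-out) estimates, and percentile
endpoints read at the adjusted levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sur import SURData, SURSpec, fit_sur_arrays, prepare_sur_data

__all__ = ["DrawSet", "BCaInterval", "bootstrap_contrasts", "bca_interval", "refit_on_indices"]

STATISTICS = ("delta_cost", "delta_effect")


@dataclass
class DrawSet:
    """B paired bootstrap draws of the adjusted (delta-cost, delta-effect)."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    B: int
    seed: int
    point_estimate: tuple[float, float]
    n: int
    n_retries: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if len(self.delta_cost) != self.B or len(self.delta_effect) != self.B:
            raise ValueError("draw count must equal B")
        if not (np.all(np.isfinite(self.delta_cost)) and np.all(np.isfinite(self.delta_effect))):
            raise ValueError("draws must be finite")

    def statistic(self, name: str) -> np.ndarray:
        if name not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")
        return self.delta_cost if name == "delta_cost" else self.delta_effect

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost, "delta_effect": self.delta_effect})


@dataclass
class BCaInterval:
    lower: float
    upper: float
    level: float
    z0: float
    acceleration: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")


def refit_on_indices(data: SURData, idx: np.ndarray) -> tuple[float, float]:
    """Arm coefficients (delta-cost, delta-effect) on a row subset."""
    b1, b2, _, _, _ = fit_sur_arrays(data, idx=idx, check=False)
    return float(b1[data.arm_idx_cost]), float(b2[data.arm_idx_effect])


def _resample_indices(rng: np.random.Generator, data: SURData, stratified: bool) -> np.ndarray:
    n = data.n
    if not stratified:
        return rng.integers(0, n, size=n)
    arm = data.X_cost[:, data.arm_idx_cost]
    idx = np.arange(n)
    parts = []
    for value in (1.0, 0.0):
        members = idx[arm == value]
        parts.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(parts)


def bootstrap_contrasts(
    table: pd.DataFrame,
    spec: SURSpec,
    B: int = 1000,
    seed: int = 0,
    stratify_by_arm: bool = False,
    max_retry_factor: int = 10,
) -> DrawSet:
    """B bootstrap replicates of the adjusted contrasts; seed-deterministic."""
    if B < 1:
        raise ValueError("B must be >= 1")
    data = prepare_sur_data(table, spec)
    point = refit_on_indices(data, np.arange(data.n))
    rng = np.random.default_rng(seed)
    dc = np.empty(B)
    de = np.empty(B)
    retries = 0
    budget = max_retry_factor * B
    b = 0
    while b < B:
        idx = _resample_indices(rng, data, stratify_by_arm)
        try:
            c, e = refit_on_indices(data, idx)
        except np.linalg.LinAlgError:
            c, e = np.nan, np.nan
        if np.isfinite(c) and np.isfinite(e):
            dc[b], de[b] = c, e
            b += 1
        else:
            retries += 1
            if retries > budget:
                raise RuntimeError(
                    f"bootstrap exhausted the retry budget ({budget}) without {B} valid refits"
                )
    return DrawSet(
        delta_cost=dc,
        delta_effect=de,
        B=B,
        seed=seed,
        point_estimate=point,
        n=data.n,
        n_retries=retries,
        stratified=stratify_by_arm,
    )


def _jackknife(data: SURData, which: int) -> np.ndarray:
    n = data.n
    out = np.empty(n)
    base = np.arange(n)
    for i in range(n):
        idx = np.delete(base, i)
        out[i] = refit_on_indices(data, idx)[which]
    return out


def bca_interval(
    draws: DrawSet,
    statistic: str,
    table: pd.DataFrame,
    spec: SURSpec,
    level: float = 0.95,
) -> BCaInterval:
    """BCa confidence interval for one of the two contrast statistics.

    Quantiles of the draw distribution are read with the
    linear-interpolation convention.  When every draw is identical a
    degenerate interval [v, v] is returned with a warning; when all
    draws fall on one side of the point estimate, z0 is clipped to the
    value implied by a half-count to keep the endpoints finite.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    theta = draws.statistic(statistic)
    which = STATISTICS.index(statistic)
    point = draws.point_estimate[which]
    if np.ptp(theta) == 0.0:
        warnings.warn("all bootstrap draws identical; returning a degenerate interval")
        return BCaInterval(float(theta[0]), float(theta[0]), level, 0.0, 0.0)

    B = draws.B
    frac_below = np.mean(theta < point)
    frac_below = min(max(frac_below, 0.5 / B), 1.0 - 0.5 / B)
    z0 = float(stats.norm.ppf(frac_below))

    data = prepare_sur_data(table, spec)
    jack = _jackknife(data, which)
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    lo_hi = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        lo_hi.append(float(np.quantile(theta, adj, method="linear")))
    return BCaInterval(lo_hi[0], lo_hi[1], level, z0, a)
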