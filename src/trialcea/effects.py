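"""Health effects: utility scoring, QALYs, and reliable improvement.

A QALY over the short follow-up horizon is the area under the linearly
interpolated utility curve between the two assessments, i.e. the mean of
the endpoint utilities times ``horizon_months / 12``.  With only two time
points every linear-interpolation reading reduces to this trapezoid.

Reliable improvement on the BSI-18 Global Severity Index (GSI, 0-72)
follows the Jacobson-Truax reliable change index: an individual reduction
is reliable when it is at least ``z * SD_ref * sqrt(2) * sqrt(1 - alpha)``
where ``SD_ref`` and Cronbach's ``alpha`` come from a reference cohort.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field

from .trial_io import UTILITY_FLOOR

__all__ = [
    "DIMENSIONS",
    "ValueSet",
    "RCIParams",
    "bundled_value_set",
    "read_value_set",
    "write_value_set",
    "score_profile",
    "all_profiles",
    "qaly_auc",
    "vas_qaly",
    "rci_threshold",
    "reliable_improvement",
]

#: EQ-5D-5L dimensions: mobility, self-care, usual activities,
#: pain/discomfort, anxiety/depression.
DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")

_INTERCEPT_KEY = "INTERCEPT"


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-5L tariff: index = intercept + per-dimension decrements.

    ``decrements[dim][level]`` holds the (non-positive) utility decrement
    for levels 2-5; level 1 contributes nothing.  The no-problem profile
    "11111" must score exactly the intercept, which must be 1.
    """

    intercept: float
    decrements: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        if abs(self.intercept - 1.0) > 1e-9:
            raise ValueError("intercept must be 1.0 so that '11111' scores 1")
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ValueError(f"missing dimension {dim}")
            decs = self.decrements[dim]
            prev = 0.0
            for level in (2, 3, 4, 5):
                if level not in decs:
                    raise ValueError(f"missing level {level} for dimension {dim}")
                d = decs[level]
                if d > 1e-12:
                    raise ValueError(f"decrement for {dim} level {level} must be <= 0")
                if d > prev + 1e-12:
                    raise ValueError(f"decrements must be non-increasing in level ({dim})")
                prev = d

    @property
    def floor(self) -> float:
        """Index of the all-level-5 profile — the lowest attainable value."""
        return self.intercept + sum(self.decrements[d][5] for d in DIMENSIONS)


def bundled_value_set() -> ValueSet:
    """Synthetic additive value set bundled for offline use.

    This is NOT a published national tariff: it is a stand-in calibrated
    so the extreme profiles score exactly 1 ("11111") and -0.661
    ("55555"), matching the range of the German EQ-5D-5L value set, with
    within-dimension decrements growing linearly in level.  Users supply
    their country's coefficient file for real analyses.
    """
    max_dec = {"MO": 0.35, "SC": 0.30, "UA": 0.30, "PD": 0.33, "AD": 0.381}
    fractions = {2: 0.25, 3: 0.5, 4: 0.75, 5: 1.0}
    decrements = {
        dim: {lvl: -max_dec[dim] * frac for lvl, frac in fractions.items()}
        for dim in DIMENSIONS
    }
    return ValueSet(intercept=1.0, decrements=decrements)


def write_value_set(vs: ValueSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["dimension", "level", "decrement"])
        writer.writerow([_INTERCEPT_KEY, 0, repr(vs.intercept)])
        for dim in DIMENSIONS:
            for level in (2, 3, 4, 5):
                writer.writerow([dim, level, repr(vs.decrements[dim][level])])


def read_value_set(path) -> ValueSet:
    """Load a value-set CSV (columns dimension, level, decrement)."""
    intercept: float | None = None
    decrements: dict[str, dict[int, float]] = {d: {} for d in DIMENSIONS}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"dimension", "level", "decrement"} <= set(
            reader.fieldnames
        ):
            raise ValueError("value-set CSV needs columns dimension, level, decrement")
        for row in reader:
            dim = row["dimension"].strip()
            if dim == _INTERCEPT_KEY:
                intercept = float(row["decrement"])
            elif dim in DIMENSIONS:
                decrements[dim][int(row["level"])] = float(row["decrement"])
            else:
                raise ValueError(f"unknown dimension {dim!r}")
    if intercept is None:
        raise ValueError("value-set CSV is missing the INTERCEPT row")
    return ValueSet(intercept=intercept, decrements=decrements)


def score_profile(profile: str, vs: ValueSet) -> float:
    """Utility index of a 5-digit EQ-5D-5L profile under a value set."""
    if len(profile) != 5 or any(c not in "12345" for c in profile):
        raise ValueError(f"profile {profile!r} must be 5 digits, each 1-5")
    total = vs.intercept
    for dim, c in zip(DIMENSIONS, profile):
        level = int(c)
        if level > 1:
            total += vs.decrements[dim][level]
    return total


def all_profiles() -> list[str]:
    """All 3125 describable health states, lexicographically ordered."""
    return ["".join(p) for p in itertools.product("12345", repeat=5)]


def qaly_auc(u_t0: float, u_t1: float, horizon_months: float = 4.0) -> float:
    """QALYs over the horizon: mean endpoint utility x horizon/12."""
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    for u in (u_t0, u_t1):
        if not (UTILITY_FLOOR - 1e-9 <= u <= 1.0 + 1e-9):
            raise ValueError(f"utility {u} outside [{UTILITY_FLOOR}, 1]")
    return (u_t0 + u_t1) / 2.0 * horizon_months / 12.0


def vas_qaly(v_t0: float, v_t1: float, horizon_months: float = 4.0) -> float:
    """QALYs from the 0-100 visual analogue scale, rescaled to [0, 1]."""
    for v in (v_t0, v_t1):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"EQ-VAS score {v} outside [0, 100]")
    return qaly_auc(v_t0 / 100.0, v_t1 / 100.0, horizon_months)


@dataclass(frozen=True)
class RCIParams:
    """Reference constants for the Jacobson-Truax reliable change index.

    ``reference_mean`` is carried as metadata only — the threshold formula
    needs just the reference SD and the scale reliability.
    """

    reference_sd: float = 7.44
    reliability: float = 0.93
    z: float = 1.96
    rounding: int = 2
    reference_mean: float = field(default=4.66, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.reliability <= 1.0):
            raise ValueError("reliability must lie in [0, 1]")
        if self.reference_sd <= 0:
            raise ValueError("reference_sd must be positive")


def rci_threshold(p: RCIParams = RCIParams()) -> float:
    """Smallest score reduction counted as reliable change.

    ``z * SD_ref * sqrt(2) * sqrt(1 - reliability)``, rounded to
    ``p.rounding`` decimals (the criterion is defined by the printed,
    rounded value; set ``rounding`` high to keep full precision).
    """
    raw = p.z * p.reference_sd * math.sqrt(2.0) * math.sqrt(1.0 - p.reliability)
    return round(raw, p.rounding)


def reliable_improvement(gsi_t0: float, gsi_t1: float, threshold: float) -> bool:
    """True when the T0->T1 GSI reduction reaches the threshold (inclusive)."""
    for g in (gsi_t0, gsi_t1):
        if not (0.0 <= g <= 72.0):
            raise ValueError(f"GSI score {g} outside [0, 72]")
    return (gsi_t0 - gsi_t1) >= threshold
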