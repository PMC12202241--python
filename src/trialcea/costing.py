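"""Unit-cost valuation of resource use, care time, and lost work.

Quantities of health-care service use are valued with standardized unit
costs inflated to a common price year with a consumer price index.
Informal and formal care hours are valued at the gross hourly wage of
care workers (substitution assumption).  Lost work — absenteeism plus
performance-weighted presenteeism — is valued at the gross hourly wage
under the human capital approach and counts only under the societal
perspective (SP); the payer perspective (PP) excludes it.

The eHealth intervention cost is added at follow-up (T1) for
intervention-arm participants only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trial_io import ParticipantRecord

__all__ = [
    "PERSPECTIVES",
    "WINDOWS",
    "INTERVENTION_CATEGORY",
    "UnitCostEntry",
    "UnitCostTable",
    "CostBreakdown",
    "default_unit_cost_table",
    "read_unit_cost_table",
    "write_unit_cost_table",
    "inflate",
    "productivity_days_lost",
    "indirect_cost",
    "cost_participant",
    "winsorize_totals",
]

PERSPECTIVES = ("SP", "PP")
WINDOWS = ("T0", "T1")

#: Reserved resource-use category holding per-participant intervention
#: euros (unit "euro"); excluded from the regular category loop.
INTERVENTION_CATEGORY = "intervention"


@dataclass(frozen=True)
class UnitCostEntry:
    unit: str
    euro_per_unit: float
    price_year: int
    #: valued at the care wage instead of euro_per_unit (care hours)
    care_wage: bool = False
    #: counted only under the societal perspective
    societal_only: bool = False

    def __post_init__(self) -> None:
        if self.euro_per_unit < 0:
            raise ValueError("euro_per_unit must be >= 0")


@dataclass
class UnitCostTable:
    """Unit costs, CPI series, wages, and costing conventions."""

    entries: dict[str, UnitCostEntry]
    cpi: dict[int, float]
    target_year: int = 2020
    care_wage_per_hour: float = 25.0
    gross_wage_per_hour: float = 30.0
    hours_per_workday: float = 8.0
    mental_health_categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for v in (self.care_wage_per_hour, self.gross_wage_per_hour, self.hours_per_workday):
            if v < 0:
                raise ValueError("wages and hours must be >= 0")

    def unit_cost(self, category: str) -> float:
        """Euro per unit at the target price year."""
        entry = self.entries[category]
        if entry.care_wage:
            return self.care_wage_per_hour
        if entry.price_year == self.target_year:
            return entry.euro_per_unit
        return inflate(entry.euro_per_unit, entry.price_year, self.target_year, self.cpi)


@dataclass
class CostBreakdown:
    """Per-category euro costs for one participant, window, perspective."""

    participant_id: str
    window: str
    perspective: str
    category_costs: dict[str, float] = field(default_factory=dict)
    intervention_cost: float = 0.0
    indirect_cost: float = 0.0

    @property
    def total(self) -> float:
        return sum(self.category_costs.values()) + self.intervention_cost + (
            self.indirect_cost if self.perspective == "SP" else 0.0
        )


def inflate(amount: float, from_year: int, to_year: int, cpi: dict[int, float]) -> float:
    """Price-adjust an amount between two years with a CPI series."""
    if from_year == to_year:
        return amount
    for year in (from_year, to_year):
        if year not in cpi:
            raise KeyError(f"CPI series is missing year {year}")
    return amount * cpi[to_year] / cpi[from_year]


def productivity_days_lost(w: float, d: float) -> float:
    """Presenteeism converted to whole lost days: (1 - w/10) x d.

    ``w`` is self-rated overall work performance on 0-10 and ``d`` the
    days at work in the recall window.
    """
    if not (0.0 <= w <= 10.0):
        raise ValueError(f"work performance {w} outside [0, 10]")
    if d < 0:
        raise ValueError("days at work must be >= 0")
    return (1.0 - w / 10.0) * d


def indirect_cost(absent_days: float, productivity_days: float, wages: UnitCostTable) -> float:
    """Human-capital valuation of lost work time at the gross wage."""
    if absent_days < 0 or productivity_days < 0:
        raise ValueError("day counts must be >= 0")
    return (absent_days + productivity_days) * wages.hours_per_workday * wages.gross_wage_per_hour


def cost_participant(
    rec: ParticipantRecord,
    window: str,
    uc: UnitCostTable,
    perspective: str = "SP",
    intervention_cost: float | None = None,
    categories: frozenset[str] | None = None,
    include_t0_indirect: bool = False,
) -> CostBreakdown:
    """Value one participant's resource use in one recall window.

    Unreported (``None``) quantities contribute nothing to the category
    sum; the complete-case decision is made downstream on totals, not
    here.  ``categories`` restricts costing to a subset (e.g. mental
    health related categories); ``None`` means every category the
    participant reports.  When ``intervention_cost`` is ``None`` the
    amount stored under the reserved ``intervention`` category is used.
    Intervention costs apply only at T1 for the IG.  Indirect costs are
    computed from the follow-up work items, so by default they enter at
    T1 only (``include_t0_indirect`` covers instruments that also ask at
    baseline).
    """
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    if perspective not in PERSPECTIVES:
        raise ValueError(f"perspective must be one of {PERSPECTIVES}")
    ru = rec.resource_use_t0 if window == "T0" else rec.resource_use_t1
    unknown = [c for c in ru if c != INTERVENTION_CATEGORY and c not in uc.entries]
    if unknown:
        raise KeyError(f"categories missing from the unit-cost table: {sorted(unknown)}")

    category_costs: dict[str, float] = {}
    for cat, qty in ru.items():
        if cat == INTERVENTION_CATEGORY or qty is None:
            continue
        if categories is not None and cat not in categories:
            continue
        entry = uc.entries[cat]
        if entry.societal_only and perspective == "PP":
            continue
        category_costs[cat] = qty * uc.unit_cost(cat)

    interv = 0.0
    if window == "T1" and rec.arm == "IG":
        if intervention_cost is not None:
            interv = intervention_cost
        else:
            stored = rec.resource_use_t1.get(INTERVENTION_CATEGORY)
            interv = float(stored) if stored is not None else 0.0

    indirect = 0.0
    if window == "T1" or include_t0_indirect:
        absent = rec.work_days_absent_t1
        days = rec.work_days_present_t1
        perf = rec.work_performance_t1
        if absent is not None or (days is not None and perf is not None):
            pres = productivity_days_lost(perf, days) if days is not None and perf is not None else 0.0
            indirect = indirect_cost(absent or 0.0, pres, uc)

    return CostBreakdown(
        participant_id=rec.participant_id,
        window=window,
        perspective=perspective,
        category_costs=category_costs,
        intervention_cost=interv,
        indirect_cost=indirect,
    )


def winsorize_totals(values, percentile: float = 95.0) -> np.ndarray:
    """Cap values above the empirical percentile at that percentile.

    The cap is the lower order-statistic quantile (``numpy``'s
    ``method="lower"``): the largest observed value at or below the
    nominal percentile position.  Unlike an interpolated quantile this
    convention makes winsorization a fixed point — applying it twice
    changes nothing — because the cap is itself a retained observation.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie strictly between 0 and 100")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot winsorize an empty collection")
    cap = np.percentile(arr[np.isfinite(arr)], percentile, method="lower")
    out = arr.copy()
    out[np.isfinite(out) & (out > cap)] = cap
    return out


# Default categories mirroring a German trial-based costing exercise.
# euro_per_unit values are round stand-ins (the national catalogue is not
# redistributable); the synthetic generator draws euro amounts and divides
# by these, so pipeline totals are unit-cost-consistent by construction.
_DEFAULT_ENTRIES: dict[str, UnitCostEntry] = {
    "inpatient_care": UnitCostEntry("day", 600.0, 2020),
    "outpatient_physician": UnitCostEntry("contact", 40.0, 2020),
    "outpatient_nonphysician": UnitCostEntry("contact", 35.0, 2020),
    "medical_aids": UnitCostEntry("item", 50.0, 2020),
    "medical_counseling": UnitCostEntry("contact", 45.0, 2020),
    "psychotherapy": UnitCostEntry("session", 90.0, 2020),
    "transportation": UnitCostEntry("trip", 15.0, 2020),
    "medication": UnitCostEntry("pack", 25.0, 2020),
    "nursing_care": UnitCostEntry("hour", 35.0, 2020),
    "informal_care": UnitCostEntry("hour", 0.0, 2020, care_wage=True),
    INTERVENTION_CATEGORY: UnitCostEntry("euro", 1.0, 2020),
}

_DEFAULT_MH = frozenset(
    {"medical_counseling", "psychotherapy", INTERVENTION_CATEGORY}
)


def default_unit_cost_table() -> UnitCostTable:
    """Stand-in unit-cost table used by the synthetic pipeline and tests."""
    return UnitCostTable(
        entries=dict(_DEFAULT_ENTRIES),
        cpi={2019: 105.3, 2020: 105.8, 2021: 109.1},
        target_year=2020,
        mental_health_categories=_DEFAULT_MH,
    )


def write_unit_cost_table(uc: UnitCostTable, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["category", "unit", "euro_per_unit", "price_year", "care_wage", "societal_only"]
        )
        for cat, e in uc.entries.items():
            writer.writerow(
                [cat, e.unit, repr(e.euro_per_unit), e.price_year, int(e.care_wage), int(e.societal_only)]
            )


def read_unit_cost_table(path, **kwargs) -> UnitCostTable:
    """Load a unit-cost CSV; CPI, wages etc. are passed as keyword args."""
    import csv

    entries: dict[str, UnitCostEntry] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"category", "unit", "euro_per_unit", "price_year"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ValueError(f"unit-cost CSV needs columns {sorted(need)}")
        for row in reader:
            entries[row["category"].strip()] = UnitCostEntry(
                unit=row["unit"].strip(),
                euro_per_unit=float(row["euro_per_unit"]),
                price_year=int(row["price_year"]),
                care_wage=bool(int(row.get("care_wage", 0) or 0)),
                societal_only=bool(int(row.get("societal_only", 0) or 0)),
            )
    kwargs.setdefault("cpi", {2020: 105.8})
    return UnitCostTable(entries=entries, **kwargs)
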