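"""Trial data model and CSV interchange.

One row per participant of a two-arm (IG vs CG) trial with a baseline
assessment (T0, 6-month resource-use recall) and one follow-up (T1,
4-month recall).  Missing numeric cells are encoded as empty strings and
surfaced as ``None`` — never silently as 0, because the complete-case
analysis downstream must distinguish "not reported" from "none used".

Resource-use quantities are open-ended category columns (``ru_t0:<cat>``,
``ru_t1:<cat>``) matched against a unit-cost table at costing time, so the
cost-category list is configuration, not code.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ARMS",
    "GENDER_IDENTITIES",
    "ANALYSIS_FLAGS",
    "UTILITY_FLOOR",
    "SCHEMA_VERSION",
    "SchemaError",
    "CohortValidationError",
    "ParticipantRecord",
    "CohortTable",
    "read_cohort",
    "write_cohort",
]

ARMS = ("IG", "CG")
GENDER_IDENTITIES = ("trans_masculine", "trans_feminine", "nonbinary")
ANALYSIS_FLAGS = ("intention_to_treat", "analysis_population", "per_protocol")

#: Lowest representable EQ-5D-5L index value (extreme problems in all
#: five dimensions under the bundled value set).
UTILITY_FLOOR = -0.661

SCHEMA_VERSION = "1"

_SCALAR_COLUMNS = (
    "participant_id",
    "arm",
    "age_years",
    "gender_identity",
    "eq5d_profile_t0",
    "eq5d_profile_t1",
    "eq5d_index_t0",
    "eq5d_index_t1",
    "eq_vas_t0",
    "eq_vas_t1",
    "gsi_t0",
    "gsi_t1",
    "work_days_absent_t1",
    "work_days_present_t1",
    "work_performance_t1",
    "analysis_flags",
)


class SchemaError(ValueError):
    """Raised when a cohort CSV does not match the documented schema."""


class CohortValidationError(ValueError):
    """Raised when one or more rows violate a field invariant.

    ``errors`` holds row-indexed human-readable diagnostics.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _valid_profile(profile: str) -> bool:
    return len(profile) == 5 and all(c in "12345" for c in profile)


@dataclass
class ParticipantRecord:
    """Outcomes, covariates, and resource use for one trial participant.

    ``None`` marks a value the participant did not report.  Resource-use
    mappings hold non-negative quantities in the units of the unit-cost
    table (visits, hours, packs, ...); a category absent from the mapping
    is "not reported", a category mapped to 0 is "reported zero use".
    """

    participant_id: str
    arm: str
    age_years: float | None = None
    gender_identity: str | None = None
    eq5d_profile_t0: str | None = None
    eq5d_profile_t1: str | None = None
    eq5d_index_t0: float | None = None
    eq5d_index_t1: float | None = None
    eq_vas_t0: float | None = None
    eq_vas_t1: float | None = None
    gsi_t0: float | None = None
    gsi_t1: float | None = None
    resource_use_t0: dict[str, float | None] = field(default_factory=dict)
    resource_use_t1: dict[str, float | None] = field(default_factory=dict)
    work_days_absent_t1: float | None = None
    work_days_present_t1: float | None = None
    work_performance_t1: float | None = None
    analysis_flags: frozenset[str] = frozenset()

    def validate(self, row: int | None = None) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        where = f"row {row}: " if row is not None else ""
        errs: list[str] = []

        def bound(name: str, value, lo, hi) -> None:
            if value is not None and not (lo <= value <= hi):
                errs.append(f"{where}{name}={value!r} outside [{lo}, {hi}]")

        if self.arm not in ARMS:
            errs.append(f"{where}arm={self.arm!r} not in {ARMS}")
        if self.gender_identity is not None and self.gender_identity not in GENDER_IDENTITIES:
            errs.append(
                f"{where}gender_identity={self.gender_identity!r} not in {GENDER_IDENTITIES}"
            )
        if self.age_years is not None and self.age_years < 0:
            errs.append(f"{where}age_years={self.age_years!r} negative")
        for name in ("eq5d_profile_t0", "eq5d_profile_t1"):
            p = getattr(self, name)
            if p is not None and not _valid_profile(p):
                errs.append(f"{where}{name}={p!r} is not a 5-digit profile with digits 1-5")
        bound("eq5d_index_t0", self.eq5d_index_t0, UTILITY_FLOOR, 1.0)
        bound("eq5d_index_t1", self.eq5d_index_t1, UTILITY_FLOOR, 1.0)
        bound("eq_vas_t0", self.eq_vas_t0, 0.0, 100.0)
        bound("eq_vas_t1", self.eq_vas_t1, 0.0, 100.0)
        bound("gsi_t0", self.gsi_t0, 0.0, 72.0)
        bound("gsi_t1", self.gsi_t1, 0.0, 72.0)
        bound("work_performance_t1", self.work_performance_t1, 0.0, 10.0)
        for name in ("work_days_absent_t1", "work_days_present_t1"):
            v = getattr(self, name)
            if v is not None and v < 0:
                errs.append(f"{where}{name}={v!r} negative")
        for win, ru in (("t0", self.resource_use_t0), ("t1", self.resource_use_t1)):
            for cat, qty in ru.items():
                if qty is not None and (not math.isfinite(qty) or qty < 0):
                    errs.append(f"{where}resource_use_{win}[{cat!r}]={qty!r} invalid")
        unknown = self.analysis_flags - set(ANALYSIS_FLAGS)
        if unknown:
            errs.append(f"{where}unknown analysis flags {sorted(unknown)}")
        return errs


@dataclass
class CohortTable:
    """An ordered collection of participants plus the two recall windows."""

    records: list[ParticipantRecord]
    recall_months_t0: float = 6.0
    recall_months_t1: float = 4.0

    def __post_init__(self) -> None:
        if self.recall_months_t0 <= 0 or self.recall_months_t1 <= 0:
            raise CohortValidationError(["recall windows must be strictly positive"])

    def validate(self) -> None:
        errs: list[str] = []
        seen: set[str] = set()
        for i, rec in enumerate(self.records):
            if rec.participant_id in seen:
                errs.append(f"row {i}: duplicate participant_id {rec.participant_id!r}")
            seen.add(rec.participant_id)
            errs.extend(rec.validate(row=i))
        if errs:
            raise CohortValidationError(errs)

    def categories(self) -> list[str]:
        """Sorted union of resource-use categories over both windows."""
        cats: set[str] = set()
        for rec in self.records:
            cats.update(rec.resource_use_t0)
            cats.update(rec.resource_use_t1)
        return sorted(cats)

    def subset(self, flag: str) -> "CohortTable":
        """Participants carrying an analysis flag, order preserved."""
        if flag not in ANALYSIS_FLAGS:
            raise ValueError(f"unknown analysis flag {flag!r}")
        return replace(self, records=[r for r in self.records if flag in r.analysis_flags])

    def __len__(self) -> int:
        return len(self.records)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def _parse_float(cell: str, name: str, row: int, errs: list[str]) -> float | None:
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        errs.append(f"row {row}: {name}={cell!r} is not numeric")
        return None


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV readable by :func:`read_cohort`.

    The first line is a ``#`` comment carrying the schema version and the
    recall windows; floats use their shortest exact representation so
    write-then-read is the identity.
    """
    cohort.validate()
    cats = cohort.categories()
    header = list(_SCALAR_COLUMNS) + [f"ru_t0:{c}" for c in cats] + [f"ru_t1:{c}" for c in cats]
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# trialcea-cohort schema_version={SCHEMA_VERSION} "
            f"recall_months_t0={_fmt(cohort.recall_months_t0)} "
            f"recall_months_t1={_fmt(cohort.recall_months_t1)}\n"
        )
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for rec in cohort.records:
            row = [
                rec.participant_id,
                rec.arm,
                _fmt(rec.age_years),
                _fmt(rec.gender_identity),
                _fmt(rec.eq5d_profile_t0),
                _fmt(rec.eq5d_profile_t1),
                _fmt(rec.eq5d_index_t0),
                _fmt(rec.eq5d_index_t1),
                _fmt(rec.eq_vas_t0),
                _fmt(rec.eq_vas_t1),
                _fmt(rec.gsi_t0),
                _fmt(rec.gsi_t1),
                _fmt(rec.work_days_absent_t1),
                _fmt(rec.work_days_present_t1),
                _fmt(rec.work_performance_t1),
                ";".join(sorted(rec.analysis_flags)),
            ]
            # "NA" = category reported but quantity missing; "" = category
            # absent from this participant's mapping altogether
            def ru_cell(ru, c):
                if c not in ru:
                    return ""
                return "NA" if ru[c] is None else _fmt(ru[c])

            row += [ru_cell(rec.resource_use_t0, c) for c in cats]
            row += [ru_cell(rec.resource_use_t1, c) for c in cats]
            writer.writerow(row)


def read_cohort(path, schema_version: str = SCHEMA_VERSION) -> CohortTable:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` for a malformed header and
    :class:`CohortValidationError` with row-indexed diagnostics for
    out-of-range values.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        recall_t0, recall_t1 = 6.0, 4.0
        if first.startswith("#"):
            meta = dict(
                tok.split("=", 1) for tok in first.lstrip("# ").split() if "=" in tok
            )
            got = meta.get("schema_version")
            if got is not None and got != schema_version:
                raise SchemaError(
                    f"schema_version {got!r} does not match expected {schema_version!r}"
                )
            recall_t0 = float(meta.get("recall_months_t0", recall_t0))
            recall_t1 = float(meta.get("recall_months_t1", recall_t1))
            reader = csv.reader(fh)
        else:
            reader = csv.reader([first.rstrip("\n")] + fh.read().splitlines())
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: no header row") from None
        missing = [c for c in _SCALAR_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        idx = {c: header.index(c) for c in _SCALAR_COLUMNS}
        ru_cols = [
            (j, c[6:], c[3:5]) for j, c in enumerate(header) if c.startswith(("ru_t0:", "ru_t1:"))
        ]

        records: list[ParticipantRecord] = []
        errs: list[str] = []
        for i, row in enumerate(reader):
            if not row:
                continue
            if len(row) != len(header):
                errs.append(f"row {i}: expected {len(header)} cells, got {len(row)}")
                continue

            def cell(name: str) -> str:
                return row[idx[name]].strip()

            def fcell(name: str) -> float | None:
                return _parse_float(cell(name), name, i, errs)

            flags = frozenset(f for f in cell("analysis_flags").split(";") if f)
            ru0: dict[str, float | None] = {}
            ru1: dict[str, float | None] = {}
            for j, cat, win in ru_cols:
                raw = row[j].strip()
                if raw == "":
                    continue
                qty = None if raw == "NA" else _parse_float(raw, f"ru_{win}:{cat}", i, errs)
                (ru0 if win == "t0" else ru1)[cat] = qty
            rec = ParticipantRecord(
                participant_id=cell("participant_id"),
                arm=cell("arm"),
                age_years=fcell("age_years"),
                gender_identity=cell("gender_identity") or None,
                eq5d_profile_t0=cell("eq5d_profile_t0") or None,
                eq5d_profile_t1=cell("eq5d_profile_t1") or None,
                eq5d_index_t0=fcell("eq5d_index_t0"),
                eq5d_index_t1=fcell("eq5d_index_t1"),
                eq_vas_t0=fcell("eq_vas_t0"),
                eq_vas_t1=fcell("eq_vas_t1"),
                gsi_t0=fcell("gsi_t0"),
                gsi_t1=fcell("gsi_t1"),
                resource_use_t0=ru0,
                resource_use_t1=ru1,
                work_days_absent_t1=fcell("work_days_absent_t1"),
                work_days_present_t1=fcell("work_days_present_t1"),
                work_performance_t1=fcell("work_performance_t1"),
                analysis_flags=flags,
            )
            errs.extend(rec.validate(row=i))
            records.append(rec)
        if errs:
            raise CohortValidationError(errs)
    cohort = CohortTable(records, recall_months_t0=recall_t0, recall_months_t1=recall_t1)
    cohort.validate()
    return cohort
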