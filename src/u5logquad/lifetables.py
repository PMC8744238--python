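"""Data model and CSV I/O for under-five life-table schedules.

A "life table" here is the vector of cumulative probabilities of dying
from birth up to each of a small set of age cut points below five years
(xq0 in demographic notation), indexed by stratum, calendar year, and
cause of death ("all" for all-cause).  On-disk collections are wide CSV
files with one column per age group; internally probabilities are always
proportions in [0, 1].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DAYS_PER_MONTH",
    "ALL_CAUSE",
    "AgeGrid",
    "LifeTableRecord",
    "LifeTableSet",
    "ValidationReport",
    "FormatError",
    "read_lifetable_csv",
    "write_lifetable_csv",
    "validate_set",
    "subset",
    "load_config",
]

#: Mean Gregorian month length in days, used whenever a day-labelled cut
#: point must be expressed in months (hazard arithmetic in the baseline).
DAYS_PER_MONTH = 30.4375

#: Cause label reserved for all-cause schedules.
ALL_CAUSE = "all"

#: Tolerance (proportion scale) for the redundant q5 column cross-check.
Q5_TOLERANCE = 1e-9

_DEFAULT_CUTPOINTS = (
    ("0-6d", 7),
    ("0-27d", 28),
    ("0-5m", 183),
    ("0-11m", 365),
    ("0-23m", 730),
    ("0-59m", 1825),
)


class FormatError(ValueError):
    """Raised when an on-disk life-table file violates the format contract."""


@dataclass(frozen=True)
class AgeGrid:
    """Ordered under-five age cut points shared by every schedule.

    Each cut point is a ``(label, upper_bound_days)`` pair; the upper bound
    is in completed days so that e.g. "0-27d" means death before exact age
    28 days. The final cut point is the under-five bound (60 months) so the
    schedule's last entry is the under-five mortality 5q0.
    """

    cutpoints: tuple[tuple[str, int], ...] = _DEFAULT_CUTPOINTS
    days_per_month: float = DAYS_PER_MONTH

    def __post_init__(self) -> None:
        if len(self.cutpoints) < 3:
            raise ValueError("AgeGrid needs at least 3 cut points")
        bounds = [b for _, b in self.cutpoints]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("cut point upper bounds must be strictly increasing")
        labels = [lab for lab, _ in self.cutpoints]
        if len(set(labels)) != len(labels):
            raise ValueError("cut point labels must be unique")
        if self.days_per_month <= 0:
            raise ValueError("days_per_month must be positive")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.cutpoints)

    @property
    def upper_bounds_days(self) -> tuple[int, ...]:
        return tuple(b for _, b in self.cutpoints)

    @property
    def terminal_label(self) -> str:
        """Label of the under-five bound (the 5q0 entry)."""
        return self.cutpoints[-1][0]

    def column_name(self, label: str) -> str:
        """CSV column name for an age label, e.g. ``0-6d`` -> ``q_0_6d``."""
        return "q_" + label.replace("-", "_")

    def months(self, label: str) -> float:
        """Upper bound of *label* expressed in months."""
        return dict(self.cutpoints)[label] / self.days_per_month

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class LifeTableRecord:
    """One stratum-year-cause schedule of cumulative death probabilities."""

    stratum: str
    year: int
    cause: str
    q: Mapping[str, float]
    q5: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.stratum, self.year, self.cause)

    def q_vector(self, grid: AgeGrid) -> np.ndarray:
        return np.array([self.q[lab] for lab in grid.labels], dtype=float)


@dataclass
class LifeTableSet:
    """A collection of life-table records on a common age grid."""

    grid: AgeGrid
    records: list[LifeTableRecord]
    units: str = "proportion"  # on-disk convention; in memory always proportion

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (stratum, year, cause) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def strata(self) -> list[str]:
        return sorted({r.stratum for r in self.records})

    @property
    def causes(self) -> list[str]:
        return sorted({r.cause for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame mirroring the CSV layout (proportion units)."""
        rows = []
        for r in self.records:
            row = {"stratum": r.stratum, "year": r.year, "cause": r.cause}
            for lab in self.grid.labels:
                row[self.grid.column_name(lab)] = r.q[lab]
            row["q5"] = r.q5
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Outcome of semantic validation of a LifeTableSet.

    ``errors`` are invariant violations (out-of-range or non-monotone
    probabilities, q5 mismatches); ``warnings`` are advisory; zero cells
    are counted per age label because they drive fitting exclusions
    (ln 0 is undefined) rather than being errors in themselves.
    """

    errors: list[tuple[tuple[str, int, str], str, str]] = field(default_factory=list)
    warnings: list[tuple[tuple[str, int, str], str, str]] = field(default_factory=list)
    n_zero_cells: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _coerce_probability(value, row_label: str, column: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row_label}: unparseable numeric in column {column!r}: {value!r}")
    if np.isnan(x):
        raise FormatError(f"row {row_label}: missing value in column {column!r}")
    return x


def read_lifetable_csv(source, units: str = "proportion", grid: AgeGrid | None = None) -> LifeTableSet:
    """Read a wide life-table CSV into a LifeTableSet (proportion units).

    Parameters
    ----------
    source
        Path or text stream. Expected header: ``stratum, year, cause``,
        one ``q_<label>`` column per grid label, and ``q5``.
    units
        ``"proportion"`` or ``"per1000"``; per-1000 inputs are divided by
        1000 on read. No sniffing is attempted.
    grid
        Age grid; defaults to the standard six under-five cut points.
    """
    if units not in ("proportion", "per1000"):
        raise ValueError(f"unknown units {units!r}; expected 'proportion' or 'per1000'")
    grid = grid or AgeGrid()
    df = pd.read_csv(source, dtype={"stratum": str, "cause": str}, float_precision="round_trip")
    required = ["stratum", "year", "cause"] + [grid.column_name(lab) for lab in grid.labels] + ["q5"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    scale = 1000.0 if units == "per1000" else 1.0

    records: list[LifeTableRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for i, row in df.iterrows():
        row_label = f"{i + 2}"  # 1-based with header line
        try:
            year = int(row["year"])
        except (TypeError, ValueError):
            raise FormatError(f"row {row_label}: unparseable year {row['year']!r}")
        key = (str(row["stratum"]), year, str(row["cause"]))
        if key in seen:
            raise FormatError(f"row {row_label}: duplicate (stratum, year, cause) key {key}")
        seen.add(key)
        q = {
            lab: _coerce_probability(row[grid.column_name(lab)], row_label, grid.column_name(lab)) / scale
            for lab in grid.labels
        }
        q5 = _coerce_probability(row["q5"], row_label, "q5") / scale
        if abs(q5 - q[grid.terminal_label]) > Q5_TOLERANCE:
            raise FormatError(
                f"row {row_label}: q5 column ({q5!r}) disagrees with terminal age column "
                f"{grid.column_name(grid.terminal_label)!r} ({q[grid.terminal_label]!r})"
            )
        records.append(LifeTableRecord(key[0], year, key[2], q, q5))
    return LifeTableSet(grid=grid, records=records, units=units)


def write_lifetable_csv(lts: LifeTableSet, target) -> None:
    """Write a LifeTableSet as a wide CSV in proportion units.

    ``read_lifetable_csv(write(...))`` round-trips bit-identically for
    proportion units (pandas repr round-trip of float64).
    """
    df = lts.to_frame()
    df.to_csv(target, index=False)


def validate_set(lts: LifeTableSet) -> ValidationReport:
    """Check every record invariant and count zero cells per age label.

    Flags out-of-range probabilities, non-monotone cumulative vectors
    (naming the offending adjacent labels), q5/terminal mismatches, and —
    when both are present — cause-specific q5 exceeding the matching
    all-cause q5. Zero cells are legal observations (e.g. no injury deaths
    yet at 7 days) and are only counted.
    """
    report = ValidationReport(n_zero_cells={lab: 0 for lab in lts.grid.labels})
    all_cause_q5 = {
        (r.stratum, r.year): r.q5 for r in lts.records if r.cause == ALL_CAUSE
    }
    for r in lts.records:
        labels = lts.grid.labels
        for lab in labels:
            v = r.q[lab]
            if not (0.0 <= v <= 1.0):
                report.errors.append((r.key, "range", f"q[{lab}]={v!r} outside [0, 1]"))
            if v == 0.0:
                report.n_zero_cells[lab] += 1
        for young, old in zip(labels, labels[1:]):
            if r.q[young] > r.q[old]:
                report.errors.append(
                    (r.key, "monotonicity", f"q[{young}]={r.q[young]!r} > q[{old}]={r.q[old]!r}")
                )
        if abs(r.q[lts.grid.terminal_label] - r.q5) > Q5_TOLERANCE:
            report.errors.append(
                (r.key, "q5-consistency", f"q5={r.q5!r} != q[{lts.grid.terminal_label}]={r.q[lts.grid.terminal_label]!r}")
            )
        if r.cause != ALL_CAUSE:
            ac = all_cause_q5.get((r.stratum, r.year))
            if ac is not None and r.q5 > ac + Q5_TOLERANCE:
                report.errors.append(
                    (r.key, "cause-exceeds-all-cause", f"cause q5={r.q5!r} > all-cause q5={ac!r}")
                )
    return report


def subset(
    lts: LifeTableSet,
    strata: Sequence[str] | None = None,
    years: Iterable[int] | None = None,
    cause: str | None = None,
    exclude_strata: Sequence[str] | None = None,
) -> LifeTableSet:
    """Filter a LifeTableSet by strata, year range, and/or cause.

    All provided filters are conjunctive; an empty result is legal. Grid
    and units are preserved.
    """
    years_set = set(years) if years is not None else None
    excl = set(exclude_strata) if exclude_strata is not None else set()
    keep = [
        r
        for r in lts.records
        if (strata is None or r.stratum in strata)
        and r.stratum not in excl
        and (years_set is None or r.year in years_set)
        and (cause is None or r.cause == cause)
    ]
    return LifeTableSet(grid=lts.grid, records=list(keep), units=lts.units)


def load_config(source) -> dict:
    """Load a YAML run configuration (age grid override, units, month length).

    Returns a dict with keys ``grid`` (AgeGrid) and ``units``; missing keys
    fall back to defaults.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read()) or {}
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    days_per_month = float(raw.get("days_per_month", DAYS_PER_MONTH))
    if "cutpoints" in raw:
        cutpoints = tuple((str(lab), int(days)) for lab, days in raw["cutpoints"])
        grid = AgeGrid(cutpoints=cutpoints, days_per_month=days_per_month)
    else:
        grid = AgeGrid(days_per_month=days_per_month)
    units = str(raw.get("units", "proportion"))
    return {"grid": grid, "units": units}
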