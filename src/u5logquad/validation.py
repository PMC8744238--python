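"""Leave-one-stratum-out cross-validation with Table-style error metrics.

Model performance is judged out of sample: for each geographic stratum
in turn, the model is fitted on the remaining strata and each held-out
life table is predicted three ways —

* ``*_k0``:        log-quadratic (or log-linear) average pattern, k = 0;
* ``*_anchored``:  k calibrated so the predicted neonatal (anchor age)
                   probability matches the held-out table's own observed
                   value exactly;
* ``standard``:    constant-hazard baseline from the held-out table's
                   observed neonatal and under-five probabilities.

Errors are the mean absolute difference |q_hat - q| per age group
(proportion scale; conventionally reported x1000 as deaths per 1000
livebirths) and the mean absolute relative difference |q_hat - q| / q
(reported as %), with observed-zero cells excluded from the relative
metric and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import standard_predict
from .lifetables import LifeTableRecord, LifeTableSet, subset
from .logquad import (
    AgeSchedule,
    CalibrationError,
    LogQuadFit,
    calibrate_k,
    fit_logquad,
    predict_pattern,
)

__all__ = ["ErrorTable", "CVReport", "error_summary", "loso_crossval"]


@dataclass
class _Cell:
    """Accumulator for one (age label, method) error cell."""

    sum_abs: float = 0.0
    sum_rel: float = 0.0
    n_cells: int = 0
    n_excluded_zero_obs: int = 0

    @property
    def mean_abs_error(self) -> float:
        return self.sum_abs / self.n_cells if self.n_cells else float("nan")

    @property
    def mean_rel_error(self) -> float:
        n_rel = self.n_cells - self.n_excluded_zero_obs
        return self.sum_rel / n_rel if n_rel else float("nan")


@dataclass
class ErrorTable:
    """Per (age label, method) mean absolute and relative errors.

    ``cells[(age_label, method)]`` carries the running sums, so fold
    tables can be pooled exactly by cell-count weighting.
    """

    cells: dict[tuple[str, str], _Cell] = field(default_factory=dict)

    def add(self, label: str, method: str, abs_err: float, rel_err: float | None) -> None:
        cell = self.cells.setdefault((label, method), _Cell())
        cell.sum_abs += abs_err
        cell.n_cells += 1
        if rel_err is None:
            cell.n_excluded_zero_obs += 1
        else:
            cell.sum_rel += rel_err

    def mean_abs_error(self, label: str, method: str) -> float:
        return self.cells[(label, method)].mean_abs_error

    def mean_rel_error(self, label: str, method: str) -> float:
        return self.cells[(label, method)].mean_rel_error

    def merge(self, other: "ErrorTable") -> None:
        for key, cell in other.cells.items():
            mine = self.cells.setdefault(key, _Cell())
            mine.sum_abs += cell.sum_abs
            mine.sum_rel += cell.sum_rel
            mine.n_cells += cell.n_cells
            mine.n_excluded_zero_obs += cell.n_excluded_zero_obs


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold and pooled error tables.

    The pooled table is the cell-count-weighted aggregate of the folds
    (an exact identity, since tables carry running sums). Per-fold tables
    are retained so equal-fold-weight averages can also be recomputed.
    """

    cause: str
    folds: list[tuple[str, ErrorTable]]
    pooled: ErrorTable
    config: dict
    fallback_records: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def methods(self) -> list[str]:
        return sorted({m for _, m in self.pooled.cells})

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: cause, fold, age, method, metric, value."""
        rows = []
        for fold_name, table in list(self.folds) + [("pooled", self.pooled)]:
            for (label, method), cell in sorted(table.cells.items()):
                common = {
                    "cause": self.cause,
                    "fold": fold_name,
                    "age_label": label,
                    "method": method,
                    "n_cells": cell.n_cells,
                    "n_excluded_zero_obs": cell.n_excluded_zero_obs,
                }
                rows.append({**common, "metric": "mean_abs_error", "value": cell.mean_abs_error})
                rows.append({**common, "metric": "mean_rel_error", "value": cell.mean_rel_error})
        return pd.DataFrame(rows)


def error_summary(
    predicted: AgeSchedule, observed: LifeTableRecord
) -> dict[str, tuple[float, float | None]]:
    """Per-age (absolute error, relative error) of a prediction.

    The relative error is ``None`` (excluded) where the observed
    probability is zero — the ratio is undefined there, and observed
    zeros are legitimate cause-specific data.
    """
    grid = predicted.grid
    missing = [lab for lab in grid.labels if lab not in observed.q]
    if missing:
        raise ValueError(f"observed record lacks grid labels {missing}")
    out: dict[str, tuple[float, float | None]] = {}
    for lab in grid.labels:
        abs_err = abs(predicted.q[lab] - observed.q[lab])
        rel_err = abs_err / observed.q[lab] if observed.q[lab] > 0 else None
        out[lab] = (abs_err, rel_err)
    return out


def loso_crossval(
    lts: LifeTableSet,
    cause: str,
    anchor_label: str = "0-27d",
    degree: int = 2,
) -> CVReport:
    """Leave-one-stratum-out cross-validation against the standard baseline.

    For each stratum s the model is fitted on all other strata's records
    of the given cause; every held-out record is then predicted with
    k = 0, with k anchored at ``anchor_label`` using the record's own
    observed q5 and anchor probability, and with the constant-hazard
    baseline from the record's observed anchor value and q5. Held-out
    records whose anchoring fails (zero anchor probability or zero
    deviation at the anchor) fall back to k = 0 and are flagged.

    ``degree=2`` labels the model columns ``logquad_*``; ``degree=1``
    (the log-linear variant) labels them ``loglinear_*``.
    """
    data = subset(lts, cause=cause)
    strata = data.strata
    if len(strata) < 2:
        raise ValueError(f"need >= 2 strata for cause {cause!r}, have {len(strata)}")
    prefix = "logquad" if degree == 2 else "loglinear"

    folds: list[tuple[str, ErrorTable]] = []
    pooled = ErrorTable()
    fallbacks: list[tuple[str, int, str]] = []
    for held_out in strata:
        fit = fit_logquad(subset(data, exclude_strata=[held_out]), cause=cause, degree=degree)
        table = ErrorTable()
        # sorted iteration: error sums independent of input record order
        for rec in sorted(subset(data, strata=[held_out]).records, key=lambda r: r.key):
            preds = {f"{prefix}_k0": predict_pattern(fit, rec.q5, k=0.0)}
            try:
                k_hat = calibrate_k(fit, rec.q5, anchor_label, rec.q[anchor_label])
            except CalibrationError:
                k_hat = 0.0
                fallbacks.append(rec.key)
            else:
                if rec.q[anchor_label] <= 0:
                    fallbacks.append(rec.key)
            preds[f"{prefix}_anchored"] = predict_pattern(fit, rec.q5, k=k_hat)
            preds["standard"] = standard_predict(lts.grid, rec.q[anchor_label], rec.q5, cause=cause)
            for method, schedule in preds.items():
                for lab, (abs_err, rel_err) in error_summary(schedule, rec).items():
                    table.add(lab, method, abs_err, rel_err)
        folds.append((held_out, table))
        pooled.merge(table)

    config = {"cause": cause, "anchor_label": anchor_label, "degree": degree, "zero_handling": "exclude"}
    return CVReport(cause=cause, folds=folds, pooled=pooled, config=config, fallback_records=fallbacks)
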