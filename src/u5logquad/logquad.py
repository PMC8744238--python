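"""The log-quadratic model of under-five age-(and cause-)specific mortality.

For each age group x the model relates the log cumulative probability of
dying from birth to x to the log under-five mortality level::

    ln q_x = a_x + b_x ln q5 + c_x (ln q5)^2 + v_x k

The coefficients (a_x, b_x, c_x) are fitted per age group by ordinary
least squares across a reference collection of life tables; v is the
leading right singular vector of the matrix of log-scale residuals (one
row per complete-case life table, one column per age group) and captures
the dominant mode of deviation from the average age pattern; the scalar k
is a per-life-table shape parameter, either zero (average pattern) or
calibrated so the predicted schedule matches an anchor age group exactly
(typically neonatal mortality, 0-27 days).

Natural logarithms are used throughout; the model is invariant to the log
base up to a rescaling of coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .lifetables import ALL_CAUSE, AgeGrid, LifeTableSet

__all__ = [
    "FitError",
    "CalibrationError",
    "LogQuadFit",
    "AgeSchedule",
    "fit_logquad",
    "predict_pattern",
    "calibrate_k",
    "enforce_monotone",
]

#: Singular values at or below this are treated as numerically zero, in
#: which case the age deviation vector v degenerates to the zero vector.
_SVD_ZERO_TOL = 1e-10


class FitError(ValueError):
    """Raised when the reference collection cannot support the fit."""


class CalibrationError(ValueError):
    """Raised when k cannot be anchored (zero deviation at the anchor age).

    Callers should fall back to k = 0 (the average pattern) and flag the
    prediction.
    """


@dataclass
class LogQuadFit:
    """Fitted log-quadratic model for one cause.

    Attributes
    ----------
    coeffs
        Per age label, the (a, b, c) OLS coefficients; c is identically 0
        for the log-linear variant (``degree=1``).
    v
        Age deviation vector: unit Euclidean norm over the included age
        labels with a non-negative entry at the youngest included label,
        or the zero vector when the residual matrix is numerically zero.
    sigma
        Per-age standard deviation of log-scale residuals after removing
        the rank-1 v*k component — the noise scale of the error term used
        by the simulation study.
    n_fit
        Per-age count of life tables entering that age's OLS (records
        with q_x > 0 and q5 > 0).
    training_k
        Per complete-case training record (keyed by (stratum, year,
        cause)), the least-squares projection of its residual vector onto
        v — for unit-norm v, the plain inner product.
    """

    grid: AgeGrid
    cause: str
    degree: int
    coeffs: dict[str, tuple[float, float, float]]
    v: dict[str, float]
    sigma: dict[str, float]
    n_fit: dict[str, int]
    training_k: dict[tuple[str, int, str], float]
    warnings_: list[str] = field(default_factory=list)

    def v_vector(self) -> np.ndarray:
        return np.array([self.v[lab] for lab in self.grid.labels])

    def sigma_vector(self) -> np.ndarray:
        return np.array([self.sigma[lab] for lab in self.grid.labels])

    def coeff_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.array([self.coeffs[lab][0] for lab in self.grid.labels])
        b = np.array([self.coeffs[lab][1] for lab in self.grid.labels])
        c = np.array([self.coeffs[lab][2] for lab in self.grid.labels])
        return a, b, c

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        """Serialize to JSON, round-tripping floats at full precision."""
        payload = {
            "cause": self.cause,
            "degree": self.degree,
            "norm_convention": "unit-euclidean, youngest-entry-nonnegative",
            "days_per_month": self.grid.days_per_month,
            "cutpoints": list(self.grid.cutpoints),
            "ages": [
                {
                    "age_label": lab,
                    "a": self.coeffs[lab][0],
                    "b": self.coeffs[lab][1],
                    "c": self.coeffs[lab][2],
                    "v": self.v[lab],
                    "sigma": self.sigma[lab],
                    "n_fit": self.n_fit[lab],
                }
                for lab in self.grid.labels
            ],
            "training_k": [
                {"stratum": s, "year": y, "cause": c, "k": k}
                for (s, y, c), k in self.training_k.items()
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LogQuadFit":
        payload = json.loads(text)
        grid = AgeGrid(
            cutpoints=tuple((lab, int(d)) for lab, d in payload["cutpoints"]),
            days_per_month=payload["days_per_month"],
        )
        coeffs, v, sigma, n_fit = {}, {}, {}, {}
        for row in payload["ages"]:
            lab = row["age_label"]
            coeffs[lab] = (row["a"], row["b"], row["c"])
            v[lab] = row["v"]
            sigma[lab] = row["sigma"]
            n_fit[lab] = row["n_fit"]
        training_k = {
            (r["stratum"], r["year"], r["cause"]): r["k"] for r in payload["training_k"]
        }
        return cls(
            grid=grid,
            cause=payload["cause"],
            degree=payload["degree"],
            coeffs=coeffs,
            v=v,
            sigma=sigma,
            n_fit=n_fit,
            training_k=training_k,
        )


@dataclass
class AgeSchedule:
    """A predicted (or observed) vector of cumulative death probabilities."""

    grid: AgeGrid
    cause: str
    q5: float
    k: float
    q: dict[str, float]
    repaired: set[str] = field(default_factory=set)

    def q_vector(self) -> np.ndarray:
        return np.array([self.q[lab] for lab in self.grid.labels])


def fit_logquad(train: LifeTableSet, cause: str = ALL_CAUSE, degree: int = 2) -> LogQuadFit:
    """Fit the log-quadratic (or log-linear) model for one cause.

    Per age label, regresses ln q_x on {1, ln q5} (``degree=1``) or
    {1, ln q5, (ln q5)^2} (``degree=2``) over records with q_x > 0 and
    q5 > 0. The residual matrix is then assembled over complete-case
    records (every age cell positive) and its first right singular vector
    becomes the age deviation vector v; per-record shape values
    ``training_k`` are the projections of residual rows onto v, and sigma
    is the per-age residual SD net of the rank-1 v*k component.

    Records with zero cells are excluded age-wise from the OLS and
    entirely from the SVD: ln 0 is undefined and imputing a floor would
    inject an arbitrary level into the age pattern.
    """
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    # sorted iteration makes the fit exactly invariant to record order
    records = sorted((r for r in train.records if r.cause == cause), key=lambda r: r.key)
    if not records:
        raise FitError(f"no records for cause {cause!r}")
    grid = train.grid
    pos = [r for r in records if r.q5 > 0]
    if len(pos) < 4:
        raise FitError(f"need >= 4 records with q5 > 0 for cause {cause!r}, have {len(pos)}")
    if len({r.q5 for r in pos}) < 3:
        raise FitError(f"need >= 3 distinct q5 values for cause {cause!r}")

    warns: list[str] = []
    coeffs: dict[str, tuple[float, float, float]] = {}
    n_fit: dict[str, int] = {}
    for lab in grid.labels:
        rows = [r for r in pos if r.q[lab] > 0]
        n_fit[lab] = len(rows)
        if len(rows) < degree + 1:
            raise FitError(f"age {lab!r}: only {len(rows)} usable records for degree-{degree} fit")
        L = np.log([r.q5 for r in rows])
        y = np.log([r.q[lab] for r in rows])
        X = np.column_stack([np.ones_like(L), L] + ([L**2] if degree == 2 else []))
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise FitError(f"age {lab!r}: rank-deficient design matrix (rank {rank})")
        a, b = beta[0], beta[1]
        c = beta[2] if degree == 2 else 0.0
        coeffs[lab] = (float(a), float(b), float(c))

    # Residual matrix over complete-case records (all age cells positive).
    complete = [r for r in pos if all(r.q[lab] > 0 for lab in grid.labels)]
    nlab = len(grid.labels)
    v = {lab: 0.0 for lab in grid.labels}
    sigma = {lab: 0.0 for lab in grid.labels}
    training_k: dict[tuple[str, int, str], float] = {}
    if len(complete) < 2:
        warns.append(
            f"fewer than 2 complete-case records ({len(complete)}); SVD skipped, v = 0"
        )
    else:
        R = np.empty((len(complete), nlab))
        for i, r in enumerate(complete):
            L = np.log(r.q5)
            for j, lab in enumerate(grid.labels):
                a, b, c = coeffs[lab]
                R[i, j] = np.log(r.q[lab]) - (a + b * L + c * L * L)
        _, s, Vt = np.linalg.svd(R, full_matrices=False)
        if s[0] <= _SVD_ZERO_TOL:
            warns.append("residual matrix numerically zero; v = 0, sigma = 0")
            vvec = np.zeros(nlab)
        else:
            vvec = Vt[0]
            # sign convention: non-negative entry at the youngest age with
            # a non-negligible component (falls through to the first label)
            for x in vvec:
                if abs(x) > _SVD_ZERO_TOL:
                    if x < 0:
                        vvec = -vvec
                    break
        v = {lab: float(vvec[j]) for j, lab in enumerate(grid.labels)}
        ks = R @ vvec  # least-squares projection; vvec is unit norm (or zero)
        training_k = {r.key: float(k) for r, k in zip(complete, ks)}
        net = R - np.outer(ks, vvec)
        sd = net.std(axis=0, ddof=1) if len(complete) > 1 else np.zeros(nlab)
        # clamp sub-round-off residue so exact constructions report sigma=0
        sd[sd <= 1e-12] = 0.0
        sigma = {lab: float(sd[j]) for j, lab in enumerate(grid.labels)}

    return LogQuadFit(
        grid=grid,
        cause=cause,
        degree=degree,
        coeffs=coeffs,
        v=v,
        sigma=sigma,
        n_fit=n_fit,
        training_k=training_k,
        warnings_=warns,
    )


def enforce_monotone(schedule: AgeSchedule) -> AgeSchedule:
    """Restrict a schedule so cumulative probabilities never decrease.

    Iterates from the oldest cut point downwards, capping each younger
    entry at the value of its elder neighbour (a right-to-left cumulative
    minimum). Ties are permitted; every modified label is recorded in
    ``repaired``. Idempotent, and never increases any entry.
    """
    labels = schedule.grid.labels
    q = dict(schedule.q)
    repaired = set(schedule.repaired)
    for young, old in zip(reversed(labels[:-1]), reversed(labels[1:])):
        if q[young] > q[old]:
            q[young] = q[old]
            repaired.add(young)
    return AgeSchedule(
        grid=schedule.grid,
        cause=schedule.cause,
        q5=schedule.q5,
        k=schedule.k,
        q=q,
        repaired=repaired,
    )


def _linear_predictor(fit: LogQuadFit, q5: float, k: float) -> np.ndarray:
    a, b, c = fit.coeff_arrays()
    L = np.log(q5)
    return a + b * L + c * L * L + fit.v_vector() * k


def predict_pattern(fit: LogQuadFit, q5: float, k: float = 0.0) -> AgeSchedule:
    """Predict the age schedule at under-five mortality level q5 and shape k.

    Evaluates q_x = exp(a + b ln q5 + c (ln q5)^2 + v k) at every age,
    repairs any monotonicity violations, and finally pins the terminal
    (60-month) entry to q5 exactly — q5 is the model's own conditioning
    variable, so the schedule must return it.
    """
    if not (0.0 < q5 <= 1.0):
        raise ValueError(f"q5 must be in (0, 1], got {q5!r}")
    qvec = np.exp(_linear_predictor(fit, q5, k))
    if np.any(qvec > 1.0):
        warnings.warn(
            f"predicted q > 1 at {int(np.sum(qvec > 1.0))} age(s); clipped (pathological extrapolation)",
            stacklevel=2,
        )
        qvec = np.minimum(qvec, 1.0)
    schedule = AgeSchedule(
        grid=fit.grid,
        cause=fit.cause,
        q5=q5,
        k=k,
        q={lab: float(qvec[j]) for j, lab in enumerate(fit.grid.labels)},
    )
    schedule = enforce_monotone(schedule)
    term = fit.grid.terminal_label
    if schedule.q[term] != q5:
        schedule.q[term] = q5
        # re-cap younger entries in case pinning lowered the terminal value
        schedule = enforce_monotone(schedule)
    return schedule


def calibrate_k(fit: LogQuadFit, q5: float, anchor_label: str = "0-27d", q_anchor: float = 0.0) -> float:
    """Solve for the shape k that reproduces q_anchor at the anchor age.

    k = (ln q_anchor - a - b ln q5 - c (ln q5)^2) / v, evaluated at the
    anchor label; ``predict_pattern`` with this k then matches q_anchor at
    the anchor exactly (to round-off), unless monotonicity repair touches
    that label.

    A zero deviation at the anchor (v[anchor] = 0) makes the anchor
    uninformative about shape and raises :class:`CalibrationError`;
    a non-positive q_anchor (e.g. zero observed neonatal deaths) warns and
    falls back to k = 0.
    """
    if anchor_label not in fit.grid.labels:
        raise ValueError(f"anchor label {anchor_label!r} not in grid")
    if not (0.0 < q5 <= 1.0):
        raise ValueError(f"q5 must be in (0, 1], got {q5!r}")
    if q_anchor <= 0.0:
        warnings.warn(
            f"non-positive anchor probability ({q_anchor!r}); falling back to k = 0",
            stacklevel=2,
        )
        return 0.0
    va = fit.v[anchor_label]
    if va == 0.0:
        raise CalibrationError(
            f"v[{anchor_label}] = 0: anchor carries no shape information; fall back to k = 0"
        )
    a, b, c = fit.coeffs[anchor_label]
    L = np.log(q5)
    return float((np.log(q_anchor) - a - b * L - c * L * L) / va)
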