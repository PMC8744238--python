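"""Synthetic MCHSS-like life-table collections with known ground truth.

Generates collections shaped like a multi-stratum child-mortality
surveillance system: six geography-by-urbanicity strata observed over
twenty years (120 strata-years), with an all-cause schedule plus two
cause-specific ones (a pneumonia-like cause concentrated in infancy and
a rarer injury-like cause rising with age). Schedules follow the
log-quadratic mechanism

    ln q_x = a_x + b_x ln q5 + c_x (ln q5)^2 + v_x k + e_x

with per-table shape k, rank-1 age deviations v, and per-age lognormal
noise, plus optional zero-inflation masking to emulate observed 0.0
cells in rare-cause data. Both the observable collection and the latent
truth (per-record k, noise draws, mask flags) are returned, so parameter
and shape recovery can be tested without any external download.

The default coefficient tables are constructed, not taken from any
empirical source: each cause's (a, b, c) are the unique parabola through
two anchor schedules — age-specific fractions of q5 at a low and a high
mortality level — with a chosen log-scale bulge at the midpoint setting
the curvature. The terminal (60-month) age group is pinned to the
identity a=0, b=1, c=0 with v = sigma = 0, so q at 60 months equals q5
by construction. No attempt is made to match any real country's levels
or trends numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetables import ALL_CAUSE, AgeGrid, LifeTableRecord, LifeTableSet

__all__ = ["CauseTruth", "TruthSpec", "default_truth", "make_mchss_like", "truth_fit"]

_DEFAULT_STRATA = (
    "east-urban",
    "east-rural",
    "mid-urban",
    "mid-rural",
    "west-urban",
    "west-rural",
)
#: Multiplier on the mid-level q5 trend per stratum (urban lower, west higher).
_DEFAULT_STRATUM_MULT = (0.55, 0.9, 0.75, 1.2, 1.0, 1.8)


@dataclass(frozen=True)
class CauseTruth:
    """True generating parameters for one cause (arrays in grid order)."""

    a: tuple[float, ...]
    b: tuple[float, ...]
    c: tuple[float, ...]
    v: tuple[float, ...]  # unit Euclidean norm, youngest entry >= 0
    sigma: tuple[float, ...]
    zero_inflation: tuple[float, ...]
    q5_start: float  # mid-stratum q5 in the first year
    q5_end: float  # mid-stratum q5 in the last year (geometric trend)
    q5_jitter_sd: float = 0.10  # lognormal jitter on the q5 trend
    k_sd: float = 1.0  # spread of the per-table shape parameter

    def __post_init__(self) -> None:
        n = len(self.a)
        for name in ("b", "c", "v", "sigma", "zero_inflation"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        vnorm = float(np.linalg.norm(self.v))
        if vnorm > 0 and abs(vnorm - 1.0) > 1e-8:
            raise ValueError("v must have unit norm (or be zero)")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma must be >= 0")
        if any(not (0.0 <= z < 1.0) for z in self.zero_inflation):
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")
        if self.a[-1] != 0.0 or self.b[-1] != 1.0 or self.c[-1] != 0.0 or self.v[-1] != 0.0:
            raise ValueError("terminal age must have (a,b,c)=(0,1,0), v=0")


@dataclass(frozen=True)
class TruthSpec:
    """Full specification of a synthetic surveillance-like collection."""

    grid: AgeGrid = field(default_factory=AgeGrid)
    causes: dict[str, CauseTruth] = field(default_factory=dict)
    strata: tuple[str, ...] = _DEFAULT_STRATA
    stratum_mult: tuple[float, ...] = _DEFAULT_STRATUM_MULT
    years: tuple[int, ...] = tuple(range(1996, 2016))

    def __post_init__(self) -> None:
        if len(self.strata) != len(self.stratum_mult):
            raise ValueError("strata and stratum_mult length mismatch")
        if len(set(self.strata)) != len(self.strata):
            raise ValueError("strata labels must be unique")
        nlab = len(self.grid.labels)
        for cause, t in self.causes.items():
            if len(t.a) != nlab:
                raise ValueError(f"cause {cause!r}: coefficient length != grid size")


def _cause_from_anchors(
    q1: float,
    q2: float,
    f1: tuple[float, ...],
    f2: tuple[float, ...],
    delta: tuple[float, ...],
    v_raw: tuple[float, ...],
    sigma: tuple[float, ...],
    zero_inflation: tuple[float, ...],
    q5_start: float,
    q5_end: float,
    k_sd: float = 1.0,
) -> CauseTruth:
    """Build (a, b, c) as the parabola through two anchor schedules.

    At q5 = q1 the schedule is f1 * q1 (age-specific fractions of q5),
    at q5 = q2 it is f2 * q2, and at the geometric midpoint the log
    probability bulges by delta relative to the chord (delta sets the
    curvature: c = -4 delta / d^2 where d = ln q2 - ln q1).
    """
    L1, L2 = np.log(q1), np.log(q2)
    d = L2 - L1
    y1 = np.log(np.array(f1) * q1)
    y2 = np.log(np.array(f2) * q2)
    m = (y2 - y1) / d
    c = -4.0 * np.array(delta) / d**2
    a = y1 - m * L1 + c * L1 * L2
    b = m - c * (L1 + L2)
    v = np.array(v_raw, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm > 0:
        v = v / nrm
    return CauseTruth(
        a=tuple(np.where(np.abs(a) < 1e-12, 0.0, a)),
        b=tuple(b),
        c=tuple(np.where(np.abs(c) < 1e-12, 0.0, c)),
        v=tuple(v),
        sigma=tuple(sigma),
        zero_inflation=tuple(zero_inflation),
        q5_start=q5_start,
        q5_end=q5_end,
        k_sd=k_sd,
    )


def default_truth(zero_inflation: bool = True) -> TruthSpec:
    """Default three-cause truth: all-cause, pneumonia-like, injury-like.

    Anchor fractions encode the intended epidemiology: all-cause
    mortality front-loaded into infancy; the pneumonia-like cause with a
    small neonatal share peaking at 0-11 months; the injury-like cause
    rare, back-loaded into ages 1-4, and zero-inflated at the youngest
    ages. ``zero_inflation=False`` switches the masking off (every cell
    positive), which is the configuration used for clean recovery tests.
    """
    zi_inj = (0.15, 0.05, 0.0, 0.0, 0.0, 0.0) if zero_inflation else (0.0,) * 6
    zi_pneu = (0.05, 0.0, 0.0, 0.0, 0.0, 0.0) if zero_inflation else (0.0,) * 6
    zi_none = (0.0,) * 6
    # The pneumonia-like curvature (delta) is deliberately pronounced: over
    # the observed mortality range ln q5 and (ln q5)^2 are nearly collinear
    # and the intercept extrapolates to ln q5 = 0, so (a, b, c) are only
    # individually identifiable at the study's sample sizes when the true
    # curvature is substantial. Magnitudes come from a design-stage variance
    # analysis of the per-age OLS (shape term v*k plus sigma as effective
    # noise), capped so the implied age schedule stays monotone for every
    # q5 in [0.001, 0.040] (checked pairwise at the anchors and at the
    # extrapolated lower scenario level).
    causes = {
        ALL_CAUSE: _cause_from_anchors(
            q1=0.008,
            q2=0.065,
            f1=(0.22, 0.38, 0.60, 0.75, 0.90, 1.0),
            f2=(0.28, 0.42, 0.62, 0.77, 0.91, 1.0),
            delta=(-0.15, -0.12, -0.08, -0.05, -0.03, 0.0),
            v_raw=(0.80, 0.65, 0.35, 0.22, 0.10, 0.0),
            sigma=(0.05, 0.04, 0.03, 0.025, 0.02, 0.0),
            zero_inflation=zi_none,
            q5_start=0.040,
            q5_end=0.012,
            k_sd=0.3,
        ),
        "pneumonia": _cause_from_anchors(
            q1=0.002,
            q2=0.040,
            f1=(0.04, 0.15, 0.50, 0.75, 0.92, 1.0),
            f2=(0.08, 0.25, 0.60, 0.82, 0.94, 1.0),
            delta=(-2.25, -1.23, -0.40, -0.17, -0.045, 0.0),
            v_raw=(0.90, 0.70, 0.35, 0.20, 0.10, 0.0),
            sigma=(0.15, 0.12, 0.10, 0.08, 0.06, 0.0),
            zero_inflation=zi_pneu,
            q5_start=0.012,
            q5_end=0.003,
        ),
        "injury": _cause_from_anchors(
            q1=0.0003,
            q2=0.005,
            f1=(0.02, 0.06, 0.25, 0.45, 0.70, 1.0),
            f2=(0.03, 0.08, 0.28, 0.48, 0.72, 1.0),
            delta=(-0.30, -0.25, -0.18, -0.12, -0.06, 0.0),
            v_raw=(0.70, 0.60, 0.35, 0.25, 0.12, 0.0),
            sigma=(0.12, 0.10, 0.08, 0.06, 0.05, 0.0),
            zero_inflation=zi_inj,
            q5_start=0.0025,
            q5_end=0.0012,
            k_sd=0.7,
        ),
    }
    return TruthSpec(causes=causes)


def truth_fit(spec: TruthSpec, cause: str):
    """Package one cause's true parameters as a LogQuadFit.

    The returned fit carries the exact generating (a, b, c, v, sigma), so
    a simulation study measuring parameter recovery compares estimates
    against known truth rather than against a refit of noisy data.
    ``training_k`` is empty — the generating shape distribution is the
    standard normal, so scenario shape values are chosen from its
    quantiles rather than from fitted projections.
    """
    from .logquad import LogQuadFit  # local import to avoid a cycle

    t = spec.causes[cause]
    labels = spec.grid.labels
    return LogQuadFit(
        grid=spec.grid,
        cause=cause,
        degree=2,
        coeffs={lab: (t.a[j], t.b[j], t.c[j]) for j, lab in enumerate(labels)},
        v={lab: t.v[j] for j, lab in enumerate(labels)},
        sigma={lab: t.sigma[j] for j, lab in enumerate(labels)},
        n_fit={lab: 0 for lab in labels},
        training_k={},
    )


def make_mchss_like(spec: TruthSpec | None = None, seed: int = 0) -> tuple[LifeTableSet, pd.DataFrame]:
    """Generate a surveillance-like LifeTableSet plus its latent truth.

    Returns ``(lts, truth)`` where ``truth`` has one row per record with
    the drawn q5, shape k, per-age noise draws ``eps_<label>``, mask
    flags ``masked_<label>``, and the count of monotonicity repairs.
    Deterministic given ``seed``. Records are monotone by construction:
    schedules are monotone-repaired after noise, and zero masks cover a
    prefix of ages (a zero cumulative probability at some age forces
    zeros at all younger ages).
    """
    spec = spec or default_truth()
    grid = spec.grid
    labels = grid.labels
    nlab = len(labels)
    rng = np.random.default_rng(seed)
    n_years = len(spec.years)

    records: list[LifeTableRecord] = []
    truth_rows: list[dict] = []
    for cause in spec.causes:
        t = spec.causes[cause]
        a, b, c = np.array(t.a), np.array(t.b), np.array(t.c)
        v, sig = np.array(t.v), np.array(t.sigma)
        zi = np.array(t.zero_inflation)
        decay = (t.q5_end / t.q5_start) ** (1.0 / max(n_years - 1, 1))
        for stratum, mult in zip(spec.strata, spec.stratum_mult):
            for iy, year in enumerate(spec.years):
                q5 = t.q5_start * decay**iy * mult * float(
                    np.exp(rng.normal(0.0, t.q5_jitter_sd))
                )
                k = float(rng.normal(0.0, t.k_sd))
                eps = rng.normal(0.0, 1.0, nlab) * sig
                L = np.log(q5)
                qvec = np.exp(a + b * L + c * L * L + v * k + eps)
                qvec[-1] = q5  # terminal age generated exactly (sigma=0, identity)
                # monotone repair (right-to-left cumulative minimum)
                repaired = 0
                for j in range(nlab - 2, -1, -1):
                    if qvec[j] > qvec[j + 1]:
                        qvec[j] = qvec[j + 1]
                        repaired += 1
                # prefix zero-masking: a mask at age j zeroes ages <= j
                masks = rng.random(nlab) < zi
                masked = np.zeros(nlab, dtype=bool)
                if masks.any():
                    masked[: int(np.max(np.nonzero(masks)[0])) + 1] = True
                qvec[masked] = 0.0
                records.append(
                    LifeTableRecord(
                        stratum=stratum,
                        year=year,
                        cause=cause,
                        q={lab: float(qvec[j]) for j, lab in enumerate(labels)},
                        q5=float(q5),
                    )
                )
                row = {"stratum": stratum, "year": year, "cause": cause, "q5_true": q5, "k": k, "n_repaired": repaired}
                row.update({f"eps_{lab}": float(eps[j]) for j, lab in enumerate(labels)})
                row.update({f"masked_{lab}": bool(masked[j]) for j, lab in enumerate(labels)})
                truth_rows.append(row)
    return LifeTableSet(grid=grid, records=records), pd.DataFrame(truth_rows)
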