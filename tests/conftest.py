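"""Shared fixtures: small hand-built life-table sets and synthetic collections."""

import numpy as np
import pytest

from u5logquad import (
    AgeGrid,
    LifeTableRecord,
    LifeTableSet,
    default_truth,
    fit_logquad,
    make_mchss_like,
)

LABELS = ("0-6d", "0-27d", "0-5m", "0-11m", "0-23m", "0-59m")


def make_set(q_rows, grid=None, cause="all", stratum="s", start_year=2000):
    """Build a LifeTableSet from a list of per-record q vectors (grid order)."""
    grid = grid or AgeGrid()
    records = [
        LifeTableRecord(
            stratum=stratum,
            year=start_year + i,
            cause=cause,
            q=dict(zip(grid.labels, map(float, row))),
            q5=float(row[-1]),
        )
        for i, row in enumerate(q_rows)
    ]
    return LifeTableSet(grid=grid, records=records)


@pytest.fixture(scope="session")
def grid():
    return AgeGrid()


@pytest.fixture(scope="session")
def identity_set(grid):
    """Ten records with q identical to q5 at every age (the identity schedule)."""
    q5s = np.linspace(0.004, 0.05, 10)
    return make_set([[q5] * 6 for q5 in q5s], grid=grid)


@pytest.fixture(scope="session")
def rank1_truth(grid):
    """Known log-linear coefficients plus a rank-1 deviation structure.

    Geometry chosen so every generated schedule stays monotone (no repair):
    age fractions of q5 at the mid level, gentle slope differences, and a
    shape vector whose per-age pushes never close the adjacent-age gaps.
    """
    frac = np.array([0.20, 0.40, 0.60, 0.74, 0.86, 1.0])
    b = np.array([1.12, 1.10, 1.08, 1.05, 1.02, 1.0])
    a = np.log(frac) + (b - 1.0) * 4.26  # fractions anchored at q5 = e^-4.26
    v = np.array([0.70, 0.55, 0.30, 0.16, 0.05, 0.0])
    v = v / np.linalg.norm(v)
    return a, b, v


def orthogonalize_shape(ks, q5s, degree=1):
    """Project shape values onto the complement of the OLS design columns.

    The per-age regressions absorb any component of the shape vector that
    lies in the span of {1, ln q5, ...}; a noise-free rank-1 construction
    therefore only reproduces its own (a, b, v, k) exactly when the shape
    values are orthogonal to the design in-sample.
    """
    L = np.log(q5s)
    X = np.column_stack([np.ones_like(L), L] + ([L**2] if degree == 2 else []))
    k = np.asarray(ks, dtype=float)
    return k - X @ np.linalg.lstsq(X, k, rcond=None)[0]


@pytest.fixture(scope="session")
def rank1_set(grid, rank1_truth):
    """Noise-free rank-1 construction: ln q = a + b ln q5 + v * k_i."""
    a, b, v = rank1_truth
    q5s = [0.005, 0.010, 0.018, 0.028, 0.040]
    ks = orthogonalize_shape([-0.5, 0.0, 0.5, 1.0, -1.0], q5s, degree=1)
    rows = []
    for q5, k in zip(q5s, ks):
        lnq = a + b * np.log(q5) + v * k
        rows.append(np.exp(lnq))
    return make_set(rows, grid=grid), q5s, list(ks)


@pytest.fixture(scope="session")
def rank1_fit(rank1_set):
    lts, _, _ = rank1_set
    return fit_logquad(lts, cause="all", degree=1)


@pytest.fixture(scope="session")
def synth_noisy():
    """Default synthetic surveillance collection (zero-inflation on)."""
    return make_mchss_like(default_truth(zero_inflation=True), seed=20250901)


@pytest.fixture(scope="session")
def synth_clean():
    """Synthetic collection without zero-inflation (all cells positive)."""
    return make_mchss_like(default_truth(zero_inflation=False), seed=20250902)


@pytest.fixture(scope="session")
def pneumonia_fit(synth_clean):
    lts, _ = synth_clean
    return fit_logquad(lts, cause="pneumonia", degree=2)
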