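"""Constant-hazard baseline ("standard approach") for under-five schedules.

When age-specific mortality is unavailable, the conventional fallback
assumes a constant mortality hazard within 0-27 days and within 1-59
months, calibrated so the schedule reproduces the observed neonatal
probability at 28 days and the under-five probability at 60 months
exactly. This module implements that interpolation on cumulative
probabilities; it applies unchanged to cause-specific probabilities
(each cause treated as its own single-decrement schedule, no
competing-risk correction).
"""

from __future__ import annotations

import math

from .lifetables import ALL_CAUSE, AgeGrid
from .logquad import AgeSchedule

__all__ = ["standard_predict"]

#: Length of the neonatal window in days; spliced to the monthly hazard
#: as exactly one month.
_NEONATAL_DAYS = 28


def standard_predict(
    grid: AgeGrid,
    q_neonatal: float,
    q5: float,
    cause: str = ALL_CAUSE,
    interpolation: str = "hazard",
) -> AgeSchedule:
    """Evaluate the constant-hazard schedule at each grid cut point.

    The daily hazard lam1 on [0, 28 d) solves 1 - exp(-28 lam1) = q_neonatal;
    the monthly hazard lam2 on [1 mo, 60 mo) solves
    (1 - q_neonatal) exp(-(T - 1) lam2) = 1 - q5 where T is the terminal cut
    point in months, so that q(28 d) = q_neonatal and q(60 mo) = q5 hold as
    exact calibration identities. Within the neonatal window
    q(t) = 1 - exp(-lam1 t_days); beyond it
    q(t) = 1 - (1 - q_neonatal) exp(-lam2 (t_months - 1)).

    ``interpolation="linear"`` interpolates the cumulative probabilities
    linearly in time within each window instead (sensitivity variant); at
    realistic magnitudes the two differ below reporting precision.
    """
    if not (0.0 <= q_neonatal <= q5 <= 1.0):
        raise ValueError(
            f"require 0 <= q_neonatal <= q5 <= 1, got q_neonatal={q_neonatal!r}, q5={q5!r}"
        )
    if q5 >= 1.0:
        raise ValueError("q5 must be < 1 (survivors must remain)")
    if interpolation not in ("hazard", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    t_last_months = grid.upper_bounds_days[-1] / grid.days_per_month
    q: dict[str, float] = {}
    if interpolation == "hazard":
        lam1 = -math.log1p(-q_neonatal) / _NEONATAL_DAYS  # per day; 0 when q_neonatal = 0
        lam2 = (math.log1p(-q_neonatal) - math.log1p(-q5)) / (t_last_months - 1.0)
        for lab, days in grid.cutpoints:
            if days <= _NEONATAL_DAYS:
                q[lab] = -math.expm1(-lam1 * days)
            else:
                t_m = days / grid.days_per_month
                q[lab] = 1.0 - (1.0 - q_neonatal) * math.exp(-lam2 * (t_m - 1.0))
    else:
        for lab, days in grid.cutpoints:
            if days <= _NEONATAL_DAYS:
                q[lab] = q_neonatal * days / _NEONATAL_DAYS
            else:
                t_m = days / grid.days_per_month
                q[lab] = q_neonatal + (q5 - q_neonatal) * (t_m - 1.0) / (t_last_months - 1.0)

    # pin the calibration identities against float residue
    for lab, days in grid.cutpoints:
        if days == _NEONATAL_DAYS:
            q[lab] = q_neonatal
    q[grid.terminal_label] = q5

    return AgeSchedule(grid=grid, cause=cause, q5=q5, k=float("nan"), q=q)
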