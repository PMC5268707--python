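"""Overdose-controlled dose assignment (escalation with overdose control).

Each new patient is dosed at the alpha-quantile of the posterior
distribution of their personalized MTD, so the posterior probability of
overdosing that patient is exactly alpha -- the *feasibility bound*.
Alpha starts conservatively (0.25) and is raised by a fixed increment per
cohort up to 0.5; at 0.5 the assignment coincides with the posterior
median.  The first patient (and the first patient of each covariate
group when groups enrol sequentially) always receives the minimum dose.
At the end of the trial the personalized MTD estimate is the posterior
median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import DoseWindow

__all__ = [
    "FeasibilitySchedule",
    "feasibility_bound",
    "next_dose",
    "final_pmtd",
]


@dataclass(frozen=True)
class FeasibilitySchedule:
    """Escalating overdose-probability bound: start, per-cohort step, cap."""

    alpha_start: float = 0.25
    alpha_step: float = 0.05
    alpha_cap: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_start <= self.alpha_cap <= 0.5:
            raise ValueError("require 0 < alpha_start <= alpha_cap <= 0.5")
        if self.alpha_step < 0.0:
            raise ValueError("alpha_step must be non-negative")


def feasibility_bound(cohort_index: int, sched: FeasibilitySchedule | None = None) -> float:
    """Feasibility bound for the 1-based ``cohort_index``-th cohort."""
    if cohort_index < 1:
        raise ValueError("cohort_index is 1-based")
    sched = sched or FeasibilitySchedule()
    return min(sched.alpha_start + (cohort_index - 1) * sched.alpha_step, sched.alpha_cap)


def next_dose(
    mtd_draws: np.ndarray,
    alpha: float,
    window: DoseWindow,
    grid: np.ndarray | None = None,
) -> float:
    """Dose for the next patient: the alpha-quantile of the posterior MTD.

    The empirical quantile uses linear interpolation of order statistics;
    the result is clamped to the dose window.  If a discrete ``grid`` of
    permitted dose levels is supplied the assignment is rounded *down* to
    the nearest level (never up, preserving the overdose-control
    guarantee); doses below the lowest level get the lowest level.
    """
    mtd_draws = np.asarray(mtd_draws, dtype=float)
    if mtd_draws.size == 0:
        raise ValueError("posterior MTD draws must be non-empty")
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    dose = window.clamp(float(np.quantile(mtd_draws, alpha)))
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        below = grid[grid <= dose]
        dose = float(below[-1]) if below.size else float(grid[0])
    return dose


def final_pmtd(mtd_draws: np.ndarray, window: DoseWindow | None = None) -> float:
    """End-of-trial personalized MTD: the posterior median, clamped."""
    mtd_draws = np.asarray(mtd_draws, dtype=float)
    if mtd_draws.size == 0:
        raise ValueError("posterior MTD draws must be non-empty")
    med = float(np.median(mtd_draws))
    return window.clamp(med) if window is not None else med
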