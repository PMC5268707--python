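"""Normalized Equivalent Toxicity Score (NETS) computation.

Phase I designs traditionally reduce a patient's toxicity response to a
single binary dose-limiting-toxicity (DLT) indicator, discarding every
non-DLT event.  The NETS system instead summarises *all* graded toxicity
events a patient experiences into a quasi-continuous severity score on
[0, 1]:

1. each CTCAE grade 0-4 event is recoded to an *adjusted grade* 0-6 that
   separates DLT from non-DLT grade 3/4 events (grade 3 DLT -> 5,
   grade 4 DLT -> 6);
2. the patient's score is driven by the worst adjusted grade, with the
   remaining toxicity burden entering through a logistic fraction so the
   score stays inside the worst grade's 1/6-wide band.

The target NETS (TNETS) plays the role the target toxicity level plays in
binary designs: the maximum tolerated dose is the dose whose average NETS
equals TNETS.  TNETS is elicited from a target toxicity profile -- the
probability that the worst event lands in each adjusted-grade band --
via a dot product with the fixed band mid-range scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MIDRANGES",
    "GRADE1_ONLY_SCORE",
    "ToxicityEvent",
    "ToxicityProfile",
    "ScoringParams",
    "TargetToxicityProfile",
    "adjust_grade",
    "max_adjusted_grade",
    "residual_burden",
    "compute_nets",
    "compute_tnets",
    "read_events",
    "score_events",
]

#: Mid-range NETS value of the band in which a profile with worst adjusted
#: grade l falls; index l = 0..6.
MIDRANGES = np.array([0.0, 0.092, 0.25, 0.417, 0.583, 0.75, 0.917])

#: Conventional score for a patient whose only toxicities are grade 1.
GRADE1_ONLY_SCORE = 1.0 / 60.0


def adjust_grade(grade: int, is_dlt: bool = False) -> int:
    """Recode a CTCAE grade plus DLT status to the 0-6 adjusted grade.

    Mapping: 0->0, 1->1, 2->2, grade 3 non-DLT->3, grade 4 non-DLT->4,
    grade 3 DLT->5, grade 4 DLT->6.  DLT status is only admissible for
    grade >= 3 events.
    """
    if grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"CTCAE grade must be an integer in 0..4, got {grade!r}")
    if is_dlt and grade < 3:
        raise ValueError(f"a grade-{grade} event cannot be dose-limiting")
    return grade + 2 if is_dlt else grade


@dataclass(frozen=True)
class ToxicityEvent:
    """One graded toxicity event.

    ``weight`` is the correlation discount r in [0, 1]: events highly
    correlated with the patient's other toxicities receive a lower weight
    so they do not double-count in the accumulated burden.  Default 1
    (no discount).
    """

    grade: int
    is_dlt: bool = False
    weight: float = 1.0

    def __post_init__(self) -> None:
        adjust_grade(self.grade, self.is_dlt)  # validates grade/DLT combo
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")

    @property
    def adjusted_grade(self) -> int:
        return adjust_grade(self.grade, self.is_dlt)


@dataclass(frozen=True)
class ToxicityProfile:
    """All toxicity events observed on one patient (possibly none)."""

    patient_id: str
    events: tuple[ToxicityEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class ScoringParams:
    """Tuning constants of the scoring formula.

    ``c`` is the intercept of the logistic fraction and ``beta_slope`` the
    rate at which additional toxicity burden pushes the score upward
    within its band; a larger slope is the more conservative choice.
    ``grade_cap`` is the normalising constant (number of non-zero
    adjusted-grade bands) and is fixed at 6.
    """

    c: float = -2.0
    beta_slope: float = 0.25
    grade_cap: int = 6

    def __post_init__(self) -> None:
        if self.grade_cap != 6:
            raise ValueError("grade_cap is the fixed normalising constant 6")
        if not 0.1 <= self.beta_slope <= 0.5:
            warnings.warn(
                f"beta_slope={self.beta_slope} is outside the recommended "
                "range [0.1, 0.5]",
                stacklevel=2,
            )


def max_adjusted_grade(profile: ToxicityProfile) -> int:
    """Worst adjusted grade over a patient's events; 0 if no toxicity."""
    if not profile.events:
        return 0
    return max(e.adjusted_grade for e in profile.events)


def residual_burden(adjusted: np.ndarray, weights: np.ndarray) -> float:
    """Default accumulation term of the scoring formula.

    Sums the weighted adjusted grades relative to the worst grade,
    excluding one instance of the worst event (the score already carries
    the worst event through its band):

        A = sum_{j != j*} w_j * g_j / g_max

    where j* is one event attaining g_max.  When several events tie for
    the worst grade the instance with the largest weight is excluded,
    which keeps the result invariant under reordering of the event list.
    """
    g_max = adjusted.max()
    tied = np.flatnonzero(adjusted == g_max)
    drop = tied[np.argmax(weights[tied])]
    keep = np.ones(adjusted.shape[0], dtype=bool)
    keep[drop] = False
    return float(np.sum(weights[keep] * adjusted[keep]) / g_max)


def compute_nets(
    profile: ToxicityProfile,
    params: ScoringParams | None = None,
    accumulation: Callable[[np.ndarray, np.ndarray], float] = residual_burden,
) -> float:
    """NETS of one patient.

    Special cases: no toxicity scores 0; a profile whose worst adjusted
    grade is 1 (grade-1 events only) scores 1/60 by convention, however
    many such events there are.  Otherwise

        S = (1/6) * [g_max - 1 + logistic(c + beta * A)]

    with A the accumulated residual burden, so S always lies inside
    ((g_max - 1)/6, g_max/6).  ``accumulation`` is pluggable so an
    alternative reading of the burden term can be swapped in without
    touching callers.
    """
    params = params or ScoringParams()
    g_max = max_adjusted_grade(profile)
    if g_max == 0:
        return 0.0
    if g_max == 1:
        return GRADE1_ONLY_SCORE
    adjusted = np.array([e.adjusted_grade for e in profile.events], dtype=float)
    weights = np.array([e.weight for e in profile.events], dtype=float)
    a = accumulation(adjusted, weights)
    frac = 1.0 / (1.0 + math.exp(-(params.c + params.beta_slope * a)))
    return (g_max - 1 + frac) / params.grade_cap


@dataclass(frozen=True)
class TargetToxicityProfile:
    """Distribution of the worst adjusted grade under treatment at the MTD.

    ``probs[l]`` is the probability that a patient treated at the MTD has
    worst adjusted grade l; the TNETS is the expectation of the band
    mid-range score under this distribution.
    """

    probs: tuple[float, ...]
    midranges: tuple[float, ...] = field(default=tuple(MIDRANGES))

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if len(probs) != 7:
            raise ValueError("probs must have one entry per adjusted grade 0..6")
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")
        if len(self.midranges) != 7:
            raise ValueError("midranges must have 7 entries")


def compute_tnets(target: TargetToxicityProfile) -> float:
    """Target NETS: expected mid-range score of the worst adjusted grade."""
    return float(np.dot(target.probs, target.midranges))


# ---------------------------------------------------------------------------
# tabular interface

_REQUIRED_COLUMNS = ("patient_id", "grade", "dlt")


def read_events(path) -> pd.DataFrame:
    """Read a toxicity-event table (CSV).

    Expected columns: patient_id, toxicity_name (optional), grade (0-4),
    dlt (0/1), weight (optional, default 1).  One row per event; a
    patient represented only by grade-0 rows scores 0.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table is missing columns {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = df["weight"].fillna(1.0)
    return df


def _profiles_from_frame(df: pd.DataFrame) -> Iterable[ToxicityProfile]:
    for pid, grp in df.groupby("patient_id", sort=True):
        events = tuple(
            ToxicityEvent(int(r.grade), bool(r.dlt), float(r.weight))
            for r in grp.itertuples()
            if int(r.grade) > 0
        )
        yield ToxicityProfile(str(pid), events)


def score_events(
    df: pd.DataFrame, params: ScoringParams | None = None
) -> pd.DataFrame:
    """Score every patient in an event table.

    Returns a frame with columns patient_id, n_events, max_adjusted_grade,
    nets -- one row per patient, sorted by patient_id.
    """
    rows = []
    for profile in _profiles_from_frame(df):
        rows.append(
            {
                "patient_id": profile.patient_id,
                "n_events": len(profile.events),
                "max_adjusted_grade": max_adjusted_grade(profile),
                "nets": compute_nets(profile, params),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "n_events", "max_adjusted_grade", "nets"])
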