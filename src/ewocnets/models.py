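"""Covariate-adjusted logistic dose-toxicity models and the MTD re-parameterization.

The mean NETS at dose x for a patient with covariate value c follows a
logistic curve

    logit mu(x, c) = beta0 + beta1 * x + delta * c

with beta1 > 0 (toxicity increases with dose).  Three models are used:

* model 1 -- no covariate (baseline pooled design);
* model 2 -- one binary covariate C in {0, 1};
* model 3 -- one continuous covariate Z in [z_min, z_max].

Rather than working with (beta0, beta1, delta) directly, the model is
re-parameterized in terms of clinically interpretable quantities:

* ``gamma_max`` -- the MTD of the covariate level with the highest MTD
  (C = 1, or Z = z_max), i.e. the dose at which the mean NETS equals the
  target theta for that level;
* ``rho1``     -- the mean NETS at the minimum dose for the *low*-MTD
  level (C = 0 / Z = z_min);
* ``rho2``     -- the mean NETS at the minimum dose for the high-MTD level.

Uniform priors on these three are easy to elicit, and the map back to the
regression coefficients is closed-form (see :func:`reparam_binary` and
:func:`reparam_continuous`).  The personalized MTD for covariate value c
follows as gamma(c) = gamma_max + (delta / beta1) * (z_max - c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "CovariateKind",
    "DoseWindow",
    "CovariateSpec",
    "ModelParams",
    "logit",
    "inv_logit",
    "reparam_none",
    "reparam_binary",
    "reparam_continuous",
    "coefficients",
    "mean_nets",
    "personalized_mtd",
    "template",
    "with_dose_grid",
]


class CovariateKind(str, Enum):
    NONE = "none"
    BINARY = "binary"
    CONTINUOUS = "continuous"


def logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError(f"logit requires p in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def inv_logit(x):
    """Numerically stable logistic function (scalar or ndarray)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DoseWindow:
    """Admissible dose range [x_min, x_max]; simulations use [0, 1]."""

    x_min: float = 0.0
    x_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be strictly below x_max")

    def clamp(self, x: float) -> float:
        return float(min(max(x, self.x_min), self.x_max))

    def contains(self, x: float) -> bool:
        return self.x_min <= x <= self.x_max


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate type and range.

    For a binary covariate the levels are {0, 1} and ``z_min``/``z_max``
    are fixed at 0/1; the high level (1 or z_max) is by convention the
    level with the higher MTD, so delta <= 0 in typical use.
    """

    kind: CovariateKind = CovariateKind.NONE
    z_min: float = 0.0
    z_max: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CovariateKind(self.kind))
        if self.kind is CovariateKind.BINARY and (self.z_min, self.z_max) != (0.0, 1.0):
            raise ValueError("binary covariates take values {0, 1}")
        if not self.z_min < self.z_max:
            raise ValueError("z_min must be strictly below z_max")


@dataclass(frozen=True)
class ModelParams:
    """Interpretable parameterization of one dose-toxicity curve.

    For ``kind == NONE`` only (gamma_max, rho1) are used and rho2 must be
    None; for the covariate models all three are required.
    """

    gamma_max: float
    rho1: float
    theta: float
    rho2: float | None = None
    window: DoseWindow = DoseWindow()
    covariate: CovariateSpec = CovariateSpec()

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if not self.window.x_min <= self.gamma_max <= self.window.x_max:
            raise ValueError("gamma_max must lie inside the dose window")
        if not 0.0 < self.rho1 < self.theta:
            raise ValueError("rho1 must be in (0, theta)")
        if self.covariate.kind is CovariateKind.NONE:
            if self.rho2 is not None:
                raise ValueError("rho2 is undefined for the no-covariate model")
        else:
            if self.rho2 is None:
                raise ValueError("rho2 is required for covariate models")
            if not 0.0 < self.rho2 < self.theta:
                raise ValueError("rho2 must be in (0, theta)")

    # -- config (de)serialization -------------------------------------------

    def to_config(self) -> dict:
        return {
            "theta": self.theta,
            "x_min": self.window.x_min,
            "x_max": self.window.x_max,
            "gamma_max": self.gamma_max,
            "rho1": self.rho1,
            "rho2": self.rho2,
            "covariate_kind": self.covariate.kind.value,
            "z_min": self.covariate.z_min,
            "z_max": self.covariate.z_max,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelParams":
        return cls(
            gamma_max=cfg["gamma_max"],
            rho1=cfg["rho1"],
            rho2=cfg.get("rho2"),
            theta=cfg["theta"],
            window=DoseWindow(cfg.get("x_min", 0.0), cfg.get("x_max", 1.0)),
            covariate=CovariateSpec(
                CovariateKind(cfg.get("covariate_kind", "none")),
                cfg.get("z_min", 0.0),
                cfg.get("z_max", 1.0),
            ),
        )


def reparam_none(params: ModelParams) -> tuple[float, float, float]:
    """(beta0, beta1, 0) for the no-covariate model.

    The curve is pinned by mean NETS rho1 at x_min and theta at gamma_max.
    """
    if params.gamma_max <= params.window.x_min:
        raise ValueError("gamma_max must exceed x_min for the slope to be defined")
    b1 = (logit(params.theta) - logit(params.rho1)) / (
        params.gamma_max - params.window.x_min
    )
    b0 = logit(params.rho1) - b1 * params.window.x_min
    return b0, b1, 0.0


def reparam_binary(params: ModelParams) -> tuple[float, float, float]:
    """(beta0, beta1, delta) for the binary-covariate model.

    beta1 = (logit theta - logit rho2) / (gamma_max - x_min)
    delta = logit rho2 - logit rho1
    beta0 = logit rho1 - beta1 * x_min
    """
    if params.covariate.kind is not CovariateKind.BINARY:
        raise ValueError("reparam_binary requires a binary covariate")
    if params.gamma_max <= params.window.x_min:
        raise ValueError("gamma_max must exceed x_min for the slope to be defined")
    lt, lr1, lr2 = logit(params.theta), logit(params.rho1), logit(params.rho2)
    b1 = (lt - lr2) / (params.gamma_max - params.window.x_min)
    delta = lr2 - lr1
    b0 = lr1 - b1 * params.window.x_min
    return b0, b1, delta


def reparam_continuous(params: ModelParams) -> tuple[float, float, float]:
    """(beta0, beta1, delta) for the continuous-covariate model.

    beta1 as in the binary model; the covariate effect is spread over the
    covariate range: delta = (logit rho2 - logit rho1) / (z_max - z_min),
    beta0 = logit rho2 - beta1 * x_min - delta * z_max.
    """
    if params.covariate.kind is not CovariateKind.CONTINUOUS:
        raise ValueError("reparam_continuous requires a continuous covariate")
    if params.gamma_max <= params.window.x_min:
        raise ValueError("gamma_max must exceed x_min for the slope to be defined")
    cov = params.covariate
    lt, lr1, lr2 = logit(params.theta), logit(params.rho1), logit(params.rho2)
    b1 = (lt - lr2) / (params.gamma_max - params.window.x_min)
    delta = (lr2 - lr1) / (cov.z_max - cov.z_min)
    b0 = lr2 - b1 * params.window.x_min - delta * cov.z_max
    return b0, b1, delta


_REPARAM = {
    CovariateKind.NONE: reparam_none,
    CovariateKind.BINARY: reparam_binary,
    CovariateKind.CONTINUOUS: reparam_continuous,
}


def coefficients(params: ModelParams) -> tuple[float, float, float]:
    """(beta0, beta1, delta) for any of the three models."""
    return _REPARAM[params.covariate.kind](params)


def mean_nets(x, cov, params: ModelParams):
    """Mean NETS mu(x, cov) on the model's logistic curve.

    ``cov`` is ignored by the no-covariate model.  Accepts scalars or
    arrays (broadcasting).
    """
    b0, b1, delta = coefficients(params)
    return inv_logit(b0 + b1 * np.asarray(x, dtype=float) + delta * np.asarray(cov, dtype=float))


def personalized_mtd(params: ModelParams, cov: float, clamp: bool = False):
    """Dose at which the mean NETS reaches theta for covariate value ``cov``.

    gamma(cov) = gamma_max + (delta / beta1) * (z_max - cov); for the
    high level (cov = z_max or binary 1) this is gamma_max itself, and
    for the no-covariate model it is gamma_max for every cov.  The raw
    root may fall outside the dose window; pass ``clamp=True`` when the
    value is to be used for dosing.
    """
    if params.covariate.kind is CovariateKind.NONE:
        g = params.gamma_max
    else:
        b0, b1, delta = coefficients(params)
        if b1 <= 0:
            raise ValueError("personalized MTD requires a positive dose slope")
        g = params.gamma_max + (delta / b1) * (params.covariate.z_max - cov)
    return params.window.clamp(g) if clamp else float(g)


def template(
    kind: CovariateKind | str,
    theta: float = 0.476,
    window: DoseWindow = DoseWindow(),
    z_min: float = 0.0,
    z_max: float = 1.0,
) -> ModelParams:
    """A ModelParams carrying only the fixed quantities of a model.

    Posterior routines need theta, the dose window and the covariate
    specification but not particular parameter values; the placeholder
    values here are the prior midpoints.
    """
    kind = CovariateKind(kind)
    mid_gamma = 0.5 * (window.x_min + window.x_max)
    return ModelParams(
        gamma_max=mid_gamma,
        rho1=theta / 2,
        rho2=None if kind is CovariateKind.NONE else theta / 2,
        theta=theta,
        window=window,
        covariate=CovariateSpec(kind, z_min, z_max)
        if kind is not CovariateKind.BINARY
        else CovariateSpec(kind, 0.0, 1.0),
    )


def with_dose_grid(window: DoseWindow, levels: np.ndarray) -> np.ndarray:
    """Validate an optional discrete dose grid inside ``window``.

    Continuous dosing is the default; a grid is only used when a protocol
    restricts assignments to pre-specified levels (round-down rule, see
    :func:`ewocnets.escalation.next_dose`).
    """
    levels = np.sort(np.asarray(levels, dtype=float))
    if levels.size == 0:
        raise ValueError("dose grid must be non-empty")
    if levels[0] < window.x_min or levels[-1] > window.x_max:
        raise ValueError("dose grid must lie inside the dose window")
    return levels
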