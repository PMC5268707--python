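"""Scenario-driven trial simulation and operating characteristics.

Eight standard scenarios (S1-S8) stress the design with a binary (S1-S4)
or continuous (S5-S8) covariate whose true effect on the MTD shrinks
from scenario to scenario: the high-level true MTD (gamma_max) is 0.5
throughout while the low-level true MTD (gamma_0) is 0.27, 0.38, 0.44
and 0.5.  A simulated trial enrols 30 patients sequentially (binary
scenarios treat the 15 high-MTD patients first, the safer order; the
continuous covariate is drawn uniform(0, 1) per patient), doses each
patient by the overdose-controlled posterior quantile, and observes a
NETS drawn from a truncated normal centred on the true dose-toxicity
curve with the quasi-Bernoulli variance mu(1 - mu).

Operating characteristics over replicate trials: mean, bias, SE and MSE
of the final gamma_max / gamma_0 estimates, the MTD+ rate (administered
doses exceeding the patient's *true* personalized MTD plus a 0.05
tolerance) and the LNETS rate (observed NETS exceeding the target theta
plus the same tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _m
from .escalation import FeasibilitySchedule, feasibility_bound, final_pmtd, next_dose
from .models import CovariateKind, CovariateSpec, DoseWindow, inv_logit, logit
from .posterior import PriorSpec, TrialData, posterior_mtd_distribution, sample_posterior

__all__ = [
    "ScenarioConfig",
    "scenario",
    "SCENARIO_IDS",
    "true_curve",
    "true_pmtd",
    "generate_nets",
    "TrialResult",
    "run_trial",
    "EstimateSummary",
    "OCReport",
    "run_study",
]

#: (covariate kind, true gamma_max, true gamma_0) for the standard scenarios.
_SCENARIOS: dict[str, tuple[CovariateKind, float, float]] = {
    "S1": (CovariateKind.BINARY, 0.5, 0.27),
    "S2": (CovariateKind.BINARY, 0.5, 0.38),
    "S3": (CovariateKind.BINARY, 0.5, 0.44),
    "S4": (CovariateKind.BINARY, 0.5, 0.5),
    "S5": (CovariateKind.CONTINUOUS, 0.5, 0.27),
    "S6": (CovariateKind.CONTINUOUS, 0.5, 0.38),
    "S7": (CovariateKind.CONTINUOUS, 0.5, 0.44),
    "S8": (CovariateKind.CONTINUOUS, 0.5, 0.5),
}

SCENARIO_IDS = tuple(_SCENARIOS)

ModelName = Literal["model1", "model2", "model3"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation condition.

    ``true_rho1`` anchors the generating curve: it is the true mean NETS
    at the minimum dose for the low-MTD covariate level (default 0.1, a
    mild-toxicity starting dose).  ``tolerance`` is the slack applied to
    both the overdosing (MTD+) and limiting-NETS counts, reflecting
    dosing on a continuous scale.
    """

    id: str
    covariate_kind: CovariateKind
    true_gamma_max: float
    true_gamma_0: float
    theta: float = 0.476
    true_rho1: float = 0.1
    n_patients: int = 30
    n_sims: int = 1000
    seed: int = 0
    tolerance: float = 0.05
    window: DoseWindow = DoseWindow(0.0, 1.0)
    z_min: float = 0.0
    z_max: float = 1.0

    def __post_init__(self) -> None:
        if self.true_gamma_0 > self.true_gamma_max:
            raise ValueError("true_gamma_0 may not exceed true_gamma_max")
        if self.true_gamma_0 <= self.window.x_min:
            raise ValueError("true_gamma_0 must exceed x_min")
        if not 0.0 < self.true_rho1 < self.theta:
            raise ValueError("true_rho1 must be in (0, theta)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")

    @property
    def covariate(self) -> CovariateSpec:
        if self.covariate_kind is CovariateKind.BINARY:
            return CovariateSpec(CovariateKind.BINARY, 0.0, 1.0)
        return CovariateSpec(CovariateKind.CONTINUOUS, self.z_min, self.z_max)


def scenario(scenario_id: str, **overrides) -> ScenarioConfig:
    """Standard scenario S1..S8, optionally with fields overridden."""
    try:
        kind, g_max, g_0 = _SCENARIOS[scenario_id]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS}")
    cfg = ScenarioConfig(
        id=scenario_id, covariate_kind=kind, true_gamma_max=g_max, true_gamma_0=g_0
    )
    return replace(cfg, **overrides) if overrides else cfg


def true_curve(sc: ScenarioConfig) -> tuple[float, float, float]:
    """Generating (beta0, beta1, delta) of a scenario's true toxicity curve.

    Three constraints pin the logistic curve: the mean NETS equals theta
    at gamma_0 for the low covariate level and at gamma_max for the high
    level, and equals true_rho1 at the minimum dose for the low level.
    """
    lt = logit(sc.theta)
    lr1 = logit(sc.true_rho1)
    z_lo = sc.covariate.z_min
    z_hi = sc.covariate.z_max
    b1 = (lt - lr1) / (sc.true_gamma_0 - sc.window.x_min)
    delta = -b1 * (sc.true_gamma_max - sc.true_gamma_0) / (z_hi - z_lo)
    b0 = lr1 - b1 * sc.window.x_min - delta * z_lo
    return b0, b1, delta


def true_pmtd(sc: ScenarioConfig, cov) -> np.ndarray:
    """True personalized MTD at covariate value(s) ``cov``.

    Linear interpolation between gamma_0 (at the low level) and
    gamma_max (at the high level) -- the exact root of the generating
    logistic curve.
    """
    spec = sc.covariate
    frac = (np.asarray(cov, dtype=float) - spec.z_min) / (spec.z_max - spec.z_min)
    return sc.true_gamma_0 + (sc.true_gamma_max - sc.true_gamma_0) * frac


def generate_nets(mu: float, rng: np.random.Generator, size=None):
    """Observed NETS: truncated normal on [0, 1], mean ``mu``, variance mu(1-mu).

    ``mu`` is the mean of the *untruncated* normal (the model's ANETS);
    the mean-variance structure matches the quasi-Bernoulli working
    likelihood.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must be in (0, 1)")
    sd = np.sqrt(mu * (1.0 - mu))
    a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
    draw = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)
    return float(draw) if size is None else draw


def _model_kind(model: ModelName) -> CovariateKind:
    return {
        "model1": CovariateKind.NONE,
        "model2": CovariateKind.BINARY,
        "model3": CovariateKind.CONTINUOUS,
    }[model]


def _normalise_model(model) -> ModelName:
    if isinstance(model, int):
        model = f"model{model}"
    if model not in ("model1", "model2", "model3"):
        raise ValueError(f"unknown model {model!r}")
    return model


@dataclass(frozen=True)
class TrialResult:
    """One simulated trial: final estimates plus the per-patient log."""

    gamma_max_hat: float
    gamma_0_hat: float
    doses: np.ndarray
    covs: np.ndarray
    nets: np.ndarray
    alphas: np.ndarray
    post_median_gamma_max: np.ndarray  # NaN where no fit preceded the dose

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_index": np.arange(1, self.doses.size + 1),
                "covariate": self.covs,
                "alpha": self.alphas,
                "assigned_dose": self.doses,
                "observed_nets": self.nets,
                "posterior_median_gamma_max": self.post_median_gamma_max,
            }
        )


def run_trial(
    sc: ScenarioConfig,
    model: ModelName | int,
    seed: int,
    n_burn: int = 1000,
    n_keep: int = 1000,
    sched: FeasibilitySchedule | None = None,
    noise: bool = True,
) -> TrialResult:
    """Simulate one adaptive trial of ``sc.n_patients`` patients.

    The fitted model may differ from the generating covariate structure:
    model1 (no covariate) can be fitted to any scenario (the baseline
    pooled design), model2 requires a binary scenario and model3 a
    continuous one.  ``noise=False`` replaces the truncated-normal NETS
    draw by the true mean (a noiseless recovery check).
    """
    model = _normalise_model(model)
    kind = _model_kind(model)
    if kind is CovariateKind.BINARY and sc.covariate_kind is not CovariateKind.BINARY:
        raise ValueError("model2 requires a binary-covariate scenario")
    if kind is CovariateKind.CONTINUOUS and sc.covariate_kind is not CovariateKind.CONTINUOUS:
        raise ValueError("model3 requires a continuous-covariate scenario")

    sched = sched or FeasibilitySchedule()
    rng = np.random.default_rng(seed)
    n = sc.n_patients
    spec = sc.covariate

    if sc.covariate_kind is CovariateKind.BINARY:
        # high-MTD group (C = 1) is treated first: the safer order
        n_high = n // 2 + n % 2
        covs = np.concatenate([np.ones(n_high), np.zeros(n - n_high)])
    else:
        covs = rng.uniform(spec.z_min, spec.z_max, size=n)

    tmpl = _m.template(kind, theta=sc.theta, window=sc.window, z_min=spec.z_min, z_max=spec.z_max)
    prior = PriorSpec.default(tmpl)
    b0, b1, delta = true_curve(sc)

    doses = np.empty(n)
    nets = np.empty(n)
    alphas = np.empty(n)
    post_medians = np.full(n, np.nan)
    seen_low_group = False
    sample = None

    for k in range(1, n + 1):
        cov_k = covs[k - 1]
        alphas[k - 1] = alpha = feasibility_bound(k, sched)
        at_start = k == 1
        if (
            sc.covariate_kind is CovariateKind.BINARY
            and kind is not CovariateKind.NONE
            and cov_k == 0.0
            and not seen_low_group
        ):
            # first patient of the second covariate group also starts low
            at_start = True
        if cov_k == 0.0 and sc.covariate_kind is CovariateKind.BINARY:
            seen_low_group = True
        if at_start:
            doses[k - 1] = sc.window.x_min
        else:
            data = TrialData(doses[: k - 1], covs[: k - 1], nets[: k - 1])
            sample = sample_posterior(
                data, prior, tmpl, seed=int(rng.integers(2**31)), n_burn=n_burn,
                n_keep=n_keep, warn_convergence=False
            )
            mtd_draws = posterior_mtd_distribution(sample, cov_k, tmpl)
            doses[k - 1] = next_dose(mtd_draws, alpha, sc.window)
            post_medians[k - 1] = float(np.median(sample.draws[:, 0]))
        mu = float(inv_logit(b0 + b1 * doses[k - 1] + delta * cov_k))
        nets[k - 1] = generate_nets(mu, rng) if noise else mu

    data = TrialData(doses, covs, nets)
    final = sample_posterior(
        data, prior, tmpl, seed=int(rng.integers(2**31)), n_burn=n_burn,
        n_keep=n_keep, warn_convergence=False
    )
    z_hi = spec.z_max if kind is not CovariateKind.NONE else 1.0
    z_lo = spec.z_min if kind is not CovariateKind.NONE else 0.0
    gmax_hat = final_pmtd(posterior_mtd_distribution(final, z_hi, tmpl), sc.window)
    g0_hat = final_pmtd(posterior_mtd_distribution(final, z_lo, tmpl), sc.window)
    return TrialResult(
        gamma_max_hat=gmax_hat,
        gamma_0_hat=g0_hat,
        doses=doses,
        covs=covs,
        nets=nets,
        alphas=alphas,
        post_median_gamma_max=post_medians,
    )


@dataclass(frozen=True)
class EstimateSummary:
    """Replicate-level summary of one estimator against its true value."""

    mean: float
    bias: float
    se: float
    mse: float


def _summarise(estimates: np.ndarray, truth: float) -> EstimateSummary:
    mean = float(np.mean(estimates))
    bias = mean - truth
    se = float(np.std(estimates))  # population SD so that mse == bias^2 + se^2
    mse = float(np.mean((estimates - truth) ** 2))
    return EstimateSummary(mean=mean, bias=bias, se=se, mse=mse)


@dataclass(frozen=True)
class OCReport:
    """Operating characteristics of one (scenario, model) study."""

    scenario_id: str
    model: str
    n_sims: int
    gamma_max: EstimateSummary
    gamma_0: EstimateSummary
    mtd_plus_pct: float
    lnets_pct: float

    def to_frame(self) -> pd.DataFrame:
        row = {
            "scenario": self.scenario_id,
            "model": self.model,
            "n_sims": self.n_sims,
            "mtd_plus_pct": self.mtd_plus_pct,
            "lnets_pct": self.lnets_pct,
        }
        for name, summ in (("gamma_max", self.gamma_max), ("gamma_0", self.gamma_0)):
            for f in ("mean", "bias", "se", "mse"):
                row[f"{name}_{f}"] = getattr(summ, f)
        return pd.DataFrame([row])


def run_study(
    sc: ScenarioConfig,
    model: ModelName | int,
    n_sims: int | None = None,
    seed: int | None = None,
    n_burn: int = 1000,
    n_keep: int = 1000,
    apply_lnets_tolerance: bool = True,
) -> OCReport:
    """Aggregate operating characteristics over replicate trials.

    Replicate i runs with seed ``seed + i`` so studies are reproducible
    and replicates can be recomputed in isolation.  MTD+ counts every
    administered dose against the dosed patient's *group- or
    z-specific* true MTD (model1 runs on covariate scenarios are judged
    against the same personalized truths, which is what exposes the
    pooled design's overdosing of the low-MTD group).  By default LNETS
    applies the scenario tolerance: observed NETS > theta + tolerance.
    """
    model = _normalise_model(model)
    n_sims = sc.n_sims if n_sims is None else n_sims
    seed = sc.seed if seed is None else seed
    if n_sims < 1:
        raise ValueError("n_sims must be positive")

    gmax_hats = np.empty(n_sims)
    g0_hats = np.empty(n_sims)
    n_over = 0
    n_lnets = 0
    n_doses = 0
    for i in range(n_sims):
        res = run_trial(sc, model, seed=seed + i, n_burn=n_burn, n_keep=n_keep)
        gmax_hats[i] = res.gamma_max_hat
        g0_hats[i] = res.gamma_0_hat
        limits = true_pmtd(sc, res.covs) + sc.tolerance
        n_over += int(np.sum(res.doses > limits))
        lnets_limit = sc.theta + (sc.tolerance if apply_lnets_tolerance else 0.0)
        n_lnets += int(np.sum(res.nets > lnets_limit))
        n_doses += res.doses.size

    return OCReport(
        scenario_id=sc.id,
        model=model,
        n_sims=n_sims,
        gamma_max=_summarise(gmax_hats, sc.true_gamma_max),
        gamma_0=_summarise(g0_hats, sc.true_gamma_0),
        mtd_plus_pct=100.0 * n_over / n_doses,
        lnets_pct=100.0 * n_lnets / n_doses,
    )
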