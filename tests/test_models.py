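"""Dose-toxicity models: re-parameterization round-trips and personalized MTD."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ewocnets.models import (
    CovariateKind,
    CovariateSpec,
    DoseWindow,
    ModelParams,
    coefficients,
    inv_logit,
    logit,
    mean_nets,
    personalized_mtd,
    reparam_binary,
    reparam_continuous,
    reparam_none,
    template,
)

THETA = 0.476


def _binary(gamma_max=0.5, rho1=0.3, rho2=0.2, theta=THETA, window=DoseWindow()):
    return ModelParams(
        gamma_max=gamma_max,
        rho1=rho1,
        rho2=rho2,
        theta=theta,
        window=window,
        covariate=CovariateSpec(CovariateKind.BINARY),
    )


def _continuous(gamma_max=0.5, rho1=0.3, rho2=0.2, z_min=0.0, z_max=1.0, theta=THETA):
    return ModelParams(
        gamma_max=gamma_max,
        rho1=rho1,
        rho2=rho2,
        theta=theta,
        covariate=CovariateSpec(CovariateKind.CONTINUOUS, z_min, z_max),
    )


def test_logit_inverse_pair():
    assert logit(0.5) == 0.0
    assert inv_logit(logit(0.3)) == pytest.approx(0.3, abs=1e-14)
    assert logit(0.476) == pytest.approx(math.log(0.476 / 0.524), abs=1e-14)
    for bad in (0.0, 1.0, -0.2, 1.3):
        with pytest.raises(ValueError):
            logit(bad)


def test_reparam_binary_closed_form():
    """Coefficients match independent logit arithmetic for a fixed triple."""
    p = _binary()
    b0, b1, delta = reparam_binary(p)
    lt = math.log(THETA / (1 - THETA))
    lr1 = math.log(0.3 / 0.7)
    lr2 = math.log(0.2 / 0.8)
    assert b1 == pytest.approx((lt - lr2) / 0.5, abs=1e-12)
    assert delta == pytest.approx(lr2 - lr1, abs=1e-12)
    assert b0 == pytest.approx(lr1, abs=1e-12)
    # round trips: theta at (gamma_max, 1), rho2 and rho1 at (x_min, 1/0)
    assert inv_logit(b0 + b1 * 0.5 + delta) == pytest.approx(THETA, abs=1e-10)
    assert inv_logit(b0 + b1 * 0.0 + delta) == pytest.approx(0.2, abs=1e-10)
    assert inv_logit(b0 + b1 * 0.0) == pytest.approx(0.3, abs=1e-10)


def test_reparam_equal_rhos_has_no_covariate_effect():
    assert reparam_binary(_binary(rho1=0.25, rho2=0.25))[2] == pytest.approx(0.0)
    assert reparam_continuous(_continuous(rho1=0.25, rho2=0.25))[2] == pytest.approx(0.0)


def test_reparam_continuous_unit_range_matches_binary():
    """On a unit covariate range the continuous slope equals the binary shift."""
    b = reparam_binary(_binary())
    c = reparam_continuous(_continuous())
    assert c[2] == pytest.approx(b[2], abs=1e-12)
    # round trips of the three defining constraints
    b0, b1, delta = c
    assert inv_logit(b0 + b1 * 0.5 + delta * 1.0) == pytest.approx(THETA, abs=1e-10)
    assert inv_logit(b0 + b1 * 0.0 + delta * 1.0) == pytest.approx(0.2, abs=1e-10)
    assert inv_logit(b0 + b1 * 0.0 + delta * 0.0) == pytest.approx(0.3, abs=1e-10)


def test_reparam_rejects_degenerate_window():
    with pytest.raises(ValueError):
        reparam_binary(_binary(gamma_max=0.0))
    with pytest.raises(ValueError):
        CovariateSpec(CovariateKind.CONTINUOUS, 0.5, 0.5)


def test_mean_nets_boundary_identities():
    p1 = ModelParams(gamma_max=0.5, rho1=0.3, theta=THETA)
    assert mean_nets(0.5, 0.0, p1) == pytest.approx(THETA, abs=1e-10)
    assert mean_nets(0.0, 0.0, p1) == pytest.approx(0.3, abs=1e-10)
    p2 = _binary()
    assert mean_nets(0.5, 1.0, p2) == pytest.approx(THETA, abs=1e-10)
    assert mean_nets(0.0, 0.0, p2) == pytest.approx(0.3, abs=1e-10)


def test_personalized_mtd_levels():
    p = _binary()
    assert personalized_mtd(p, 1.0) == pytest.approx(0.5)
    b0, b1, _ = reparam_binary(p)
    lt = math.log(THETA / (1 - THETA))
    gamma0_direct = (lt - b0) / b1  # root of the cov = 0 curve
    assert personalized_mtd(p, 0.0) == pytest.approx(gamma0_direct, abs=1e-12)
    flat = _binary(rho1=0.25, rho2=0.25)
    assert personalized_mtd(flat, 0.0) == pytest.approx(0.5)
    pooled = ModelParams(gamma_max=0.4, rho1=0.3, theta=THETA)
    assert personalized_mtd(pooled, 0.7) == pytest.approx(0.4)


def test_personalized_mtd_clamps_for_dosing():
    """Extrapolating beyond the observed covariate range can leave the window;
    the dosing variant clamps while the raw root is kept for reporting."""
    p = _continuous(rho1=0.4, rho2=0.01, gamma_max=0.9)
    raw = personalized_mtd(p, 3.0)  # covariate far above z_max
    assert raw > 1.0
    assert personalized_mtd(p, 3.0, clamp=True) == 1.0


_rho = st.floats(0.01, THETA - 0.01)
_gamma = st.floats(0.05, 1.0)


@given(_gamma, _rho, _rho)
def test_reparam_round_trip_property(gamma, rho1, rho2):
    """(gamma_max, rho1, rho2) -> coefficients -> curve recovers all three anchors."""
    p = _binary(gamma_max=gamma, rho1=rho1, rho2=rho2)
    b0, b1, delta = coefficients(p)
    assert b1 > 0  # rho2 < theta and gamma_max > x_min guarantee a rising curve
    assert (delta < 0) == (rho2 < rho1) or rho1 == rho2
    assert inv_logit(b0 + b1 * gamma + delta) == pytest.approx(THETA, abs=1e-10)
    assert inv_logit(b0 + delta) == pytest.approx(rho2, abs=1e-10)
    assert inv_logit(b0) == pytest.approx(rho1, abs=1e-10)


@given(_gamma, _rho, _rho, st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_personalized_mtd_monotone_when_high_level_safer(gamma, rho1, rho2, z1, z2):
    """delta <= 0 makes the personalized MTD non-decreasing in the covariate."""
    if rho2 > rho1:
        rho1, rho2 = rho2, rho1
    p = _continuous(gamma_max=gamma, rho1=rho1, rho2=rho2)
    lo, hi = sorted((z1, z2))
    assert personalized_mtd(p, lo) <= personalized_mtd(p, hi) + 1e-12


def test_config_round_trip():
    p = _continuous(gamma_max=0.7, rho1=0.11, rho2=0.07)
    q = ModelParams.from_config(p.to_config())
    assert q == p
    p1 = ModelParams(gamma_max=0.5, rho1=0.3, theta=THETA)
    assert ModelParams.from_config(p1.to_config()) == p1


def test_template_carries_fixed_quantities():
    t = template("binary", theta=0.4)
    assert t.theta == 0.4
    assert t.covariate.kind is CovariateKind.BINARY
    with pytest.raises(ValueError):
        ModelParams(gamma_max=0.5, rho1=0.3, rho2=0.2, theta=THETA)  # rho2 without covariate
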