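"""Quasi-Bernoulli posterior: likelihood oracle, prior recovery, concentration."""

import math

import numpy as np
import pytest
from scipy import stats

from ewocnets.models import (
    CovariateKind,
    CovariateSpec,
    ModelParams,
    coefficients,
    inv_logit,
    template,
)
from ewocnets.posterior import (
    PosteriorSample,
    PriorSpec,
    TrialData,
    posterior_mtd_distribution,
    quasi_loglik,
    sample_posterior,
)

THETA = 0.476
TMPL = template("binary", theta=THETA)
PRIOR = PriorSpec.default(TMPL)


def test_quasi_loglik_degenerate_outcomes():
    """s = 0 contributes log(1 - mu); s = 1 contributes log(mu)."""
    data0 = TrialData([0.3], [1.0], [0.0])
    data1 = TrialData([0.3], [1.0], [1.0])
    p = ModelParams(0.5, 0.2, THETA, 0.1, covariate=CovariateSpec(CovariateKind.BINARY))
    b0, b1, d = coefficients(p)
    mu = inv_logit(b0 + b1 * 0.3 + d)
    assert quasi_loglik(0.5, 0.2, 0.1, data0, TMPL) == pytest.approx(math.log(1 - mu))
    assert quasi_loglik(0.5, 0.2, 0.1, data1, TMPL) == pytest.approx(math.log(mu))


def test_quasi_loglik_matches_direct_product():
    """Log-likelihood equals the log of the brute-force Bernoulli-form product."""
    x = [0.0, 0.25, 0.5]
    c = [1.0, 0.0, 1.0]
    s = [0.1, 0.35, 0.6]
    data = TrialData(x, c, s)
    p = ModelParams(0.5, 0.2, THETA, 0.1, covariate=CovariateSpec(CovariateKind.BINARY))
    b0, b1, d = coefficients(p)
    prod = 1.0
    for xi, ci, si in zip(x, c, s):
        mu = 1.0 / (1.0 + math.exp(-(b0 + b1 * xi + d * ci)))
        prod *= mu**si * (1.0 - mu) ** (1.0 - si)
    assert quasi_loglik(0.5, 0.2, 0.1, data, TMPL) == pytest.approx(
        math.log(prod), abs=1e-12
    )


def test_prior_recovery_with_empty_data():
    """No observations: all three marginals reproduce their uniform priors."""
    samp = sample_posterior(TrialData.empty(), PRIOR, TMPL, seed=9)
    crit = 1.628 / math.sqrt(samp.n_keep)  # 1% Kolmogorov-Smirnov critical value
    assert stats.kstest(samp.draws[:, 0], "uniform").statistic < crit
    for j in (1, 2):
        assert stats.kstest(samp.draws[:, j], "uniform", args=(0, THETA)).statistic < crit
    assert samp.draws[:, 0].mean() == pytest.approx(0.5, abs=0.03)


def test_same_seed_gives_identical_draws():
    data = TrialData([0.0, 0.2], [1.0, 1.0], [0.1, 0.3])
    a = sample_posterior(data, PRIOR, TMPL, seed=42)
    b = sample_posterior(data, PRIOR, TMPL, seed=42)
    assert np.array_equal(a.draws, b.draws)
    assert a.acceptance_rate == b.acceptance_rate
    c = sample_posterior(data, PRIOR, TMPL, seed=43)
    assert not np.array_equal(a.draws, c.draws)


def test_draws_stay_in_prior_box_and_acceptance_is_reasonable():
    rng = np.random.default_rng(5)
    data = TrialData(rng.uniform(0, 1, 30), (np.arange(30) < 15).astype(float), rng.uniform(0, 1, 30))
    samp = sample_posterior(data, PRIOR, TMPL, seed=7)
    assert samp.draws[:, 0].min() >= 0.0 and samp.draws[:, 0].max() <= 1.0
    assert samp.draws[:, 1:].min() >= 0.0 and samp.draws[:, 1:].max() <= THETA
    assert 0.05 < samp.acceptance_rate < 0.8


def test_posterior_mean_matches_grid_oracle(grid_marginal_means):
    """MCMC marginal means agree with dense quadrature within 0.01."""
    x = np.array([0.0, 0.2, 0.4, 0.3, 0.5])
    c = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
    s = np.array([0.05, 0.20, 0.45, 0.55, 0.60])
    data = TrialData(x, c, s)
    oracle = grid_marginal_means(data, THETA, "binary")
    samp = sample_posterior(data, PRIOR, TMPL, seed=3, n_burn=2000, n_keep=20000)
    for j in range(3):
        assert samp.draws[:, j].mean() == pytest.approx(oracle[j], abs=0.01)


def test_posterior_concentrates_with_sample_size():
    """RMSE of the posterior median of gamma_max falls as n grows (10 -> 30 -> 100).

    Uses mean-correct Beta noise (a member of the quasi-Bernoulli
    mean-variance family), under which the quasi-posterior is consistent.
    The adaptive-trial generator's truncated normal is deliberately not
    used here: its truncation biases the outcome mean away from the curve
    except near 0.5, so static uniform dosing under it converges to a
    pseudo-true parameter rather than the truth.
    """
    true = ModelParams(
        0.65, 0.3, THETA, 0.15, covariate=CovariateSpec(CovariateKind.BINARY)
    )
    b0, b1, d = coefficients(true)
    rmses = []
    for n in (10, 30, 100):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.05, 0.95, n)
            c = (rng.random(n) < 0.5).astype(float)
            mu = inv_logit(b0 + b1 * x + d * c)
            s = rng.beta(8 * mu, 8 * (1 - mu))
            samp = sample_posterior(TrialData(x, c, s), PRIOR, TMPL, seed=1000 + seed)
            errs.append(np.median(samp.draws[:, 0]) - 0.65)
        rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
    assert rmses[0] > rmses[1] > rmses[2]


def test_mtd_distribution_transforms():
    """Hand-computed transform of explicit draws; high level returns gamma draws."""
    draws = np.array(
        [
            [0.5, 0.30, 0.20],
            [0.4, 0.10, 0.10],
            [0.6, 0.25, 0.05],
            [0.7, 0.40, 0.40],
            [0.3, 0.20, 0.15],
        ]
    )
    samp = PosteriorSample(draws, ("gamma_max", "rho1", "rho2"), 0, 0, 5, 1.0, float("nan"))
    assert np.allclose(posterior_mtd_distribution(samp, 1.0, TMPL), draws[:, 0])
    got = posterior_mtd_distribution(samp, 0.0, TMPL)
    lt = math.log(THETA / (1 - THETA))
    for k in range(5):
        g, r1, r2 = draws[k]
        lr1 = math.log(r1 / (1 - r1))
        lr2 = math.log(r2 / (1 - r2))
        b1 = (lt - lr2) / g
        expected = g + (lr2 - lr1) / b1
        assert got[k] == pytest.approx(expected, abs=1e-12)
    # equal rhos: the covariate is inert and every level has the same MTD
    flat = np.array([[0.5, 0.2, 0.2], [0.4, 0.3, 0.3]])
    samp_flat = PosteriorSample(flat, ("gamma_max", "rho1", "rho2"), 0, 0, 2, 1.0, float("nan"))
    assert np.allclose(posterior_mtd_distribution(samp_flat, 0.3, TMPL), flat[:, 0])


def test_optional_delta_sign_constraint():
    samp = sample_posterior(
        TrialData.empty(), PRIOR, TMPL, seed=11, enforce_delta_nonpositive=True
    )
    assert np.all(samp.draws[:, 2] <= samp.draws[:, 1])


def test_no_covariate_model_samples_two_parameters(tmp_path):
    tmpl1 = template("none", theta=THETA)
    samp = sample_posterior(TrialData.empty(), PriorSpec.default(tmpl1), tmpl1, seed=2)
    assert samp.draws.shape[1] == 2
    assert samp.param_names == ("gamma_max", "rho1")
    from ewocnets.posterior import save_draws

    out = tmp_path / "draws.csv"
    save_draws(samp, out)
    assert out.exists() and (tmp_path / "draws.csv.meta.json").exists()
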