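"""Shared fixtures: deterministic hypothesis profile and a quadrature oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid_marginal_means():
    """3-D quadrature oracle for posterior marginal means.

    Integrates exp(quasi-loglik) over the prior box (gamma_max, rho1,
    rho2) on a dense rectangle rule and returns the marginal posterior
    means -- an estimate independent of the Metropolis-Hastings path.
    """

    def _compute(data, theta: float, kind: str, n_grid: int = 160):
        from ewocnets.models import logit

        g = np.linspace(0.0, 1.0, n_grid + 2)[1:-1]
        r = np.linspace(0.0, theta, n_grid + 2)[1:-1]
        G, R1, R2 = np.meshgrid(g, r, r, indexing="ij")
        lt = logit(theta)
        LR1 = np.log(R1 / (1 - R1))
        LR2 = np.log(R2 / (1 - R2))
        B1 = (lt - LR2) / G
        if kind == "binary":
            D = LR2 - LR1
            B0 = LR1
        else:  # continuous on [0, 1]
            D = LR2 - LR1
            B0 = LR2 - D
        ll = np.zeros_like(G)
        for xi, ci, si in zip(data.x, data.cov, data.nets):
            mu = 1.0 / (1.0 + np.exp(-(B0 + B1 * xi + D * ci)))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            ll += si * np.log(mu) + (1.0 - si) * np.log1p(-mu)
        w = np.exp(ll - ll.max())
        z = w.sum()
        return (
            float((w * G).sum() / z),
            float((w * R1).sum() / z),
            float((w * R2).sum() / z),
        )

    return _compute
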