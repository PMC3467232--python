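"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from srtlearn.pipeline import records_to_frame
from srtlearn.task_model import default_cohort, simulate_cohort


def lds_brute_force(params, y, inputs):
    """Joint-Gaussian oracle for the scalar-state LDS.

    Builds the explicit n x n covariance of the latent states by
    propagating each noise source through the A-recursion, conditions the
    Gaussian on the observed entries of y, and returns (smoothed means,
    smoothed variances, log-likelihood).  Independent of the Kalman
    recursion it is used to check.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    u = inputs.prev_press_onehot @ params.b + params.f * inputs.prev_error
    dk = inputs.cue_onehot @ params.d
    mx = np.empty(n)
    mx[0] = params.x1_mean
    for t in range(1, n):
        mx[t] = params.a * mx[t - 1] + u[t]
    T = np.zeros((n, n))
    for t in range(n):
        for s in range(t + 1):
            T[t, s] = params.a ** (t - s)
    vars_w = np.full(n, params.q)
    vars_w[0] = params.x1_var
    Sx = T @ np.diag(vars_w) @ T.T
    Sy = Sx + np.eye(n) * params.r
    my = mx + dk
    obs = np.isfinite(y)
    Syo = Sy[np.ix_(obs, obs)]
    resid = y[obs] - my[obs]
    sol = np.linalg.solve(Syo, resid)
    _, logdet = np.linalg.slogdet(Syo)
    ll = -0.5 * (obs.sum() * np.log(2 * np.pi) + logdet + resid @ sol)
    C = Sx[:, obs]
    m_s = mx + C @ sol
    V_s = Sx - C @ np.linalg.solve(Syo, C.T)
    return m_s, np.diag(V_s).copy(), float(ll)


def acf_brute_force(x, n_lags):
    """Definitional biased autocovariance-ratio oracle (double loop)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    c0 = sum(x[t] * x[t] for t in range(n))
    rho = np.empty(n_lags)
    for lag in range(1, n_lags + 1):
        acc = 0.0
        for t in range(n - lag):
            acc += x[t] * x[t + lag]
        rho[lag - 1] = acc / c0
    return rho


@pytest.fixture(scope="session")
def small_cohort_frame():
    """Six default-profile synthetic subjects, full 10-day tables."""
    return records_to_frame(simulate_cohort(default_cohort(n_subjects=6, seed=2026)))
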