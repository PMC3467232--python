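"""AR(1) response-binding toy model with its closed-form ACF oracle.

On each trial the internal response plan is an AR(1) process around a
fixed mean, x_t = mu_P + alpha * (x_{t-1} - mu_P) + N(0, sigma_P^2), and
the observable response adds independent execution noise,
y_t = x_t + N(0, sigma_E^2).  With alpha = 0 successive plans (and hence
responses) are statistically independent; as alpha grows the responses
become temporally correlated, which is the signature the chunk estimator
looks for.  The theoretical response ACF is

    rho(l) = alpha^l * sigma_x^2 / (sigma_x^2 + sigma_E^2),
    sigma_x^2 = sigma_P^2 / (1 - alpha^2),

which serves as the analytic oracle for the simulated curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = ["BindingConfig", "simulate_binding", "theoretical_acf", "block_acfs", "mean_block_acf"]


@dataclass(frozen=True)
class BindingConfig:
    """Simulation settings; defaults follow the reference simulation
    (mu_P = 200 ms, sigma_P = sigma_E = 10 ms, 100 blocks x 1000 trials)."""

    alpha: float
    mu_p_ms: float = 200.0
    sigma_p_ms: float = 10.0
    sigma_e_ms: float = 10.0
    n_blocks: int = 100
    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1) for stationarity")
        if self.sigma_p_ms < 0 or self.sigma_e_ms < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_blocks < 1 or self.n_trials < 2:
            raise ValueError("need >= 1 block of >= 2 trials")


def simulate_binding(config: BindingConfig) -> np.ndarray:
    """Simulated responses y, shape (n_blocks, n_trials); deterministic given seed.

    The first plan of every block is drawn from the stationary distribution
    so block-level ACFs need no burn-in.
    """
    rng = np.random.default_rng(config.seed)
    a, sp, se = config.alpha, config.sigma_p_ms, config.sigma_e_ms
    shape = (config.n_blocks, config.n_trials)
    eps = rng.normal(0.0, sp, size=shape)
    if a == 0.0 or sp == 0.0:
        x = eps
    else:
        x0 = rng.normal(0.0, sp / np.sqrt(1.0 - a * a), size=config.n_blocks)
        x, _ = lfilter([1.0], [1.0, -a], eps, axis=1, zi=(a * x0)[:, None])
    return config.mu_p_ms + x + rng.normal(0.0, se, size=shape)


def theoretical_acf(alpha: float, sigma_p: float, sigma_e: float, lag) -> np.ndarray | float:
    """Closed-form response autocorrelation at the given lag(s) >= 1."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    lag = np.asarray(lag)
    if np.any(lag < 1):
        raise ValueError("lags must be >= 1")
    if sigma_p == 0.0 and sigma_e == 0.0:
        raise ValueError("ACF undefined for a noiseless (constant) process")
    var_x = sigma_p**2 / (1.0 - alpha**2)
    out = alpha**lag.astype(float) * var_x / (var_x + sigma_e**2)
    return float(out) if out.ndim == 0 else out


def block_acfs(y: np.ndarray, n_lags: int, center: str = "global") -> np.ndarray:
    """Biased per-block ACF profiles, shape (n_blocks, n_lags), lags 1..n_lags.

    With ``center='global'`` (default) every block is centered on the grand
    mean: the blocks share one stationary mean, and per-block centering
    would inject an O(1/n_trials) negative bias into each block's ACF.
    ``center='block'`` reproduces the per-block-mean convention.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n_blocks, n = y.shape
    if n <= n_lags:
        raise ValueError("blocks shorter than the requested lag span")
    if center == "global":
        x = y - y.mean()
    elif center == "block":
        x = y - y.mean(axis=1, keepdims=True)
    else:
        raise ValueError("center must be 'global' or 'block'")
    c0 = np.einsum("ij,ij->i", x, x)
    acfs = np.empty((n_blocks, n_lags))
    for lag in range(1, n_lags + 1):
        acfs[:, lag - 1] = np.einsum("ij,ij->i", x[:, :-lag], x[:, lag:]) / c0
    return acfs


def mean_block_acf(y: np.ndarray, n_lags: int, center: str = "global") -> np.ndarray:
    """Across-block mean of :func:`block_acfs`; lags 1..n_lags."""
    return block_acfs(y, n_lags, center=center).mean(axis=0)
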