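"""Linear dynamical system of trial-by-trial response preparedness.

A scalar latent state X_t (in ms) captures how prepared the subject is to
respond fast on trial t: negative values are prepared/fast trials, positive
values hesitations.  The model is

    state:   X_t = A * X_{t-1} + B . Y_t + F * e_t + w_t,   w_t ~ N(0, Q)
    output:  y_t = X_t + D . K_t + v_t,                     v_t ~ N(0, R)

where K_t is the 8-long one-hot of the presented cue, Y_t the one-hot of
the key pressed on the *previous* trial (regardless of accuracy; zero after
an omission or on the first trial), and e_t indicates an error on the
previous trial.  A is the state memory, B the per-key response prediction,
D the per-key response bias, F the error-corrective state delay, and Q/R
the state and motor noise variances — all in RT units (ms / ms^2).

Inference is an exact scalar Kalman filter + RTS smoother; fitting is
expectation-maximization with closed-form M-steps (joint regression for
A, B, F; per-key means for D; residual variances for Q, R), so the
marginal log-likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import DegenerateInputError, EmDivergenceError

__all__ = [
    "N_KEYS",
    "LdsParams",
    "LdsInputs",
    "StateTrajectory",
    "EmResult",
    "build_inputs",
    "lds_predict_observe",
    "kalman_smooth",
    "em_fit",
    "default_init",
    "simulate_lds",
]

N_KEYS = 8
_VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class LdsParams:
    a: float                      # state memory (dimensionless)
    b: np.ndarray                 # response prediction per key, ms
    d: np.ndarray                 # response bias per key, ms
    f: float                      # error-corrective delay, ms
    q: float                      # state noise variance, ms^2
    r: float                      # motor noise variance, ms^2
    x1_mean: float = 0.0
    x1_var: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        if self.b.shape != (N_KEYS,) or self.d.shape != (N_KEYS,):
            raise ValueError("b and d must be 8-vectors")
        if self.q < 0 or self.r < 0 or self.x1_var < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class LdsInputs:
    """Per-trial design: cue one-hots, previous-press one-hots, previous-error flags."""

    cue_onehot: np.ndarray        # (n, 8)
    prev_press_onehot: np.ndarray  # (n, 8); row t refers to the press on trial t-1
    prev_error: np.ndarray        # (n,); 1 if trial t-1 was an error

    @property
    def n_trials(self) -> int:
        return self.cue_onehot.shape[0]


@dataclass(frozen=True)
class StateTrajectory:
    smoothed_means: np.ndarray
    smoothed_vars: np.ndarray
    lag1_cov: np.ndarray          # cov(x_{t+1}, x_t | y), length n-1
    loglik: float


@dataclass(frozen=True)
class EmResult:
    params: LdsParams
    trajectories: list[StateTrajectory]
    loglik_path: np.ndarray
    n_iter: int
    converged: bool


def _onehot(keys: np.ndarray) -> np.ndarray:
    out = np.zeros((keys.size, N_KEYS))
    valid = (keys >= 1) & (keys <= N_KEYS)
    out[np.flatnonzero(valid), keys[valid].astype(int) - 1] = 1.0
    return out


def build_inputs(
    cues,
    presses,
    errors,
    rts=None,
    b_input: str = "binary",
) -> LdsInputs:
    """Assemble the per-trial design matrices from raw block vectors.

    ``presses`` uses 0/NaN/None-as-0 for omissions.  With
    ``b_input='rt'`` the previous-press one-hot is scaled by the previous
    trial's mean-centered RT (the alternative reading in which B weights
    the previous reaction time rather than the press identity).
    """
    cues = np.asarray(cues, dtype=float)
    presses = np.asarray(
        [0 if p is None or (isinstance(p, float) and not np.isfinite(p)) else p for p in presses],
        dtype=float,
    )
    errors = np.asarray(errors, dtype=float)
    n = cues.size
    K = _onehot(cues)
    Y = np.zeros((n, N_KEYS))
    Y[1:] = _onehot(presses[:-1])
    if b_input == "rt":
        if rts is None:
            raise ValueError("b_input='rt' requires the rts vector")
        rt = np.asarray(rts, dtype=float)
        centered = np.where(np.isfinite(rt), rt - np.nanmean(rt), 0.0)
        Y[1:] *= centered[:-1, None]
    elif b_input != "binary":
        raise ValueError("b_input must be 'binary' or 'rt'")
    e = np.zeros(n)
    e[1:] = errors[:-1]
    return LdsInputs(cue_onehot=K, prev_press_onehot=Y, prev_error=e)


def lds_predict_observe(
    params: LdsParams, x_t: float, cue_onehot, prev_press_onehot, prev_error: float
) -> tuple[float, float]:
    """Deterministic one-step means: (next state mean, current output mean)."""
    y_mean = x_t + float(params.d @ np.asarray(cue_onehot, dtype=float))
    x_next = (
        params.a * x_t
        + float(params.b @ np.asarray(prev_press_onehot, dtype=float))
        + params.f * float(prev_error)
    )
    return x_next, y_mean


def _state_inputs(params: LdsParams, inputs: LdsInputs) -> np.ndarray:
    """u_t = B . Y_t + F * e_t for every trial (u_0 is unused)."""
    return inputs.prev_press_onehot @ params.b + params.f * inputs.prev_error


def kalman_smooth(params: LdsParams, y, inputs: LdsInputs) -> StateTrajectory:
    """Exact filter + RTS smoother; NaN observations propagate without update."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if inputs.n_trials != n:
        raise ValueError("y and inputs must cover the same trials")
    u = _state_inputs(params, inputs)
    dk = inputs.cue_onehot @ params.d

    m_pred = np.empty(n)
    v_pred = np.empty(n)
    m_filt = np.empty(n)
    v_filt = np.empty(n)
    loglik = 0.0
    m_pred[0], v_pred[0] = params.x1_mean, params.x1_var
    for t in range(n):
        if np.isfinite(y[t]):
            s = v_pred[t] + params.r
            if s <= 0.0:
                raise DegenerateInputError(
                    "singular innovation variance (Q = R = 0 with an observed trial)"
                )
            innov = y[t] - (m_pred[t] + dk[t])
            gain = v_pred[t] / s
            m_filt[t] = m_pred[t] + gain * innov
            v_filt[t] = (1.0 - gain) * v_pred[t]
            loglik += -0.5 * (np.log(2.0 * np.pi * s) + innov * innov / s)
        else:
            m_filt[t] = m_pred[t]
            v_filt[t] = v_pred[t]
        if t + 1 < n:
            m_pred[t + 1] = params.a * m_filt[t] + u[t + 1]
            v_pred[t + 1] = params.a**2 * v_filt[t] + params.q

    m_s = np.empty(n)
    v_s = np.empty(n)
    lag1 = np.empty(max(n - 1, 0))
    m_s[-1], v_s[-1] = m_filt[-1], v_filt[-1]
    for t in range(n - 2, -1, -1):
        j = params.a * v_filt[t] / v_pred[t + 1] if v_pred[t + 1] > 0 else 0.0
        m_s[t] = m_filt[t] + j * (m_s[t + 1] - m_pred[t + 1])
        v_s[t] = v_filt[t] + j * j * (v_s[t + 1] - v_pred[t + 1])
        lag1[t] = j * v_s[t + 1]
    return StateTrajectory(
        smoothed_means=m_s, smoothed_vars=v_s, lag1_cov=lag1, loglik=float(loglik)
    )


def default_init(blocks: Sequence[tuple[np.ndarray, LdsInputs]]) -> LdsParams:
    """Standard EM starting point: A = 0.5, B = F = 0, D = per-key mean RT,
    Q = R = half the residual variance around the per-key means."""
    d = np.zeros(N_KEYS)
    counts = np.zeros(N_KEYS)
    for y, inputs in blocks:
        obs = np.isfinite(np.asarray(y, dtype=float))
        d += inputs.cue_onehot[obs].T @ np.asarray(y, dtype=float)[obs]
        counts += inputs.cue_onehot[obs].sum(axis=0)
    overall = d.sum() / max(counts.sum(), 1.0)
    d = np.where(counts > 0, d / np.maximum(counts, 1.0), overall)
    rss, n_obs = 0.0, 0
    for y, inputs in blocks:
        yv = np.asarray(y, dtype=float)
        obs = np.isfinite(yv)
        resid = yv[obs] - inputs.cue_onehot[obs] @ d
        rss += float(resid @ resid)
        n_obs += int(obs.sum())
    var = max(rss / max(n_obs, 1), 1.0)
    q = r = var / 2.0
    return LdsParams(
        a=0.5, b=np.zeros(N_KEYS), d=d, f=0.0, q=q, r=r, x1_mean=0.0, x1_var=10.0 * q
    )


def _as_blocks(y, inputs) -> list[tuple[np.ndarray, LdsInputs]]:
    if isinstance(y, (list, tuple)) and inputs is None:
        return [(np.asarray(b, dtype=float), i) for b, i in y]
    return [(np.asarray(y, dtype=float), inputs)]


def em_fit(
    y,
    inputs: Optional[LdsInputs] = None,
    init: Optional[LdsParams] = None,
    max_iter: int = 200,
    rel_tol: float = 1e-6,
    fit_b: bool = True,
) -> EmResult:
    """Fit the LDS by EM on one block or a list of ``(y, inputs)`` blocks.

    The E-step is :func:`kalman_smooth` per block; the M-step solves the
    state-equation regression for (A, B, F) jointly from the expected
    sufficient statistics, sets D to per-cue mean deviations, and updates
    Q and R from expected residuals.  The initial-state prior (mean 0,
    variance 10 x the initial Q) is held fixed throughout so the likelihood
    is guaranteed non-decreasing.  Stops when the relative log-likelihood
    improvement drops below ``rel_tol``.
    """
    blocks = _as_blocks(y, inputs)
    params = init if init is not None else default_init(blocks)
    n_coef = 1 + N_KEYS + 1  # [x_{t-1}, Y_t(8), e_t]
    loglik_path: list[float] = []
    converged = False
    trajectories: list[StateTrajectory] = []

    for it in range(max_iter):
        trajectories = [kalman_smooth(params, yb, ib) for yb, ib in blocks]
        ll = sum(tr.loglik for tr in trajectories)
        if not np.isfinite(ll):
            raise EmDivergenceError("log-likelihood became non-finite", it)
        loglik_path.append(ll)
        if len(loglik_path) >= 2:
            prev = loglik_path[-2]
            if ll - prev < rel_tol * (abs(prev) + 1.0):
                converged = True
                break

        # --- M-step: state equation (A, B, F) and Q -------------------
        G = np.zeros((n_coef, n_coef))
        h = np.zeros(n_coef)
        sxx = 0.0
        n_state = 0
        for (yb, ib), tr in zip(blocks, trajectories):
            m, v, c = tr.smoothed_means, tr.smoothed_vars, tr.lag1_cov
            U = np.column_stack([ib.prev_press_onehot, ib.prev_error])[1:]  # (n-1, 9)
            mp, mc = m[:-1], m[1:]
            ex2_prev = v[:-1] + mp * mp
            G[0, 0] += ex2_prev.sum()
            G[0, 1:] += mp @ U
            G[1:, 1:] += U.T @ U
            h[0] += (c + mc * mp).sum()
            h[1:] += mc @ U
            sxx += (v[1:] + mc * mc).sum()
            n_state += mc.size
        G[1:, 0] = G[0, 1:]
        if not fit_b:
            keep = [0, n_coef - 1]
            theta = np.zeros(n_coef)
            sub = np.linalg.lstsq(G[np.ix_(keep, keep)], h[keep], rcond=None)[0]
            theta[keep] = sub
        else:
            theta = np.linalg.lstsq(G, h, rcond=None)[0]
        if not np.isfinite(theta).all():
            raise EmDivergenceError("state regression produced non-finite coefficients", it)
        q_new = (sxx - 2.0 * theta @ h + theta @ G @ theta) / max(n_state, 1)
        q_new = max(float(q_new), _VAR_FLOOR)

        # --- M-step: output equation (D) and R ------------------------
        d_num = np.zeros(N_KEYS)
        d_cnt = np.zeros(N_KEYS)
        for (yb, ib), tr in zip(blocks, trajectories):
            obs = np.isfinite(yb)
            resid = yb[obs] - tr.smoothed_means[obs]
            d_num += ib.cue_onehot[obs].T @ resid
            d_cnt += ib.cue_onehot[obs].sum(axis=0)
        d_new = np.where(d_cnt > 0, d_num / np.maximum(d_cnt, 1.0), params.d)
        rss = 0.0
        n_obs = 0
        for (yb, ib), tr in zip(blocks, trajectories):
            obs = np.isfinite(yb)
            e = yb[obs] - tr.smoothed_means[obs] - ib.cue_onehot[obs] @ d_new
            rss += float(e @ e + tr.smoothed_vars[obs].sum())
            n_obs += int(obs.sum())
        r_new = max(rss / max(n_obs, 1), _VAR_FLOOR)

        params = replace(
            params,
            a=float(theta[0]),
            b=theta[1 : 1 + N_KEYS].copy(),
            f=float(theta[-1]),
            q=q_new,
            d=d_new,
            r=r_new,
        )

    return EmResult(
        params=params,
        trajectories=trajectories,
        loglik_path=np.asarray(loglik_path),
        n_iter=len(loglik_path),
        converged=converged,
    )


def simulate_lds(
    params: LdsParams,
    cue_sequence,
    error_sequence,
    seed: int = 0,
    b_input: str = "binary",
) -> tuple[np.ndarray, LdsInputs, np.ndarray]:
    """Sample (y, inputs, latent x) from the model with exogenous errors.

    The pressed key equals the cue on correct trials and a uniformly random
    other key on error trials.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    cues = np.asarray(cue_sequence, dtype=int)
    errors = np.asarray(error_sequence, dtype=float)
    n = cues.size
    if errors.size != n:
        raise ValueError("cue and error sequences must have equal length")
    presses = cues.copy()
    err_idx = np.flatnonzero(errors > 0)
    if err_idx.size:
        presses[err_idx] = (cues[err_idx] - 1 + rng.integers(1, N_KEYS, err_idx.size)) % N_KEYS + 1
    inputs = build_inputs(cues, presses, errors, b_input=b_input)
    u = _state_inputs(params, inputs)
    x = np.empty(n)
    x[0] = params.x1_mean + rng.normal(0.0, np.sqrt(params.x1_var))
    w = rng.normal(0.0, np.sqrt(params.q), size=n)
    for t in range(1, n):
        x[t] = params.a * x[t - 1] + u[t] + w[t]
    y = x + inputs.cue_onehot @ params.d + rng.normal(0.0, np.sqrt(params.r), size=n)
    return y, inputs, x
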