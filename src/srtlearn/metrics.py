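"""Sequence-specific learning metrics and learner classification.

Sequence-specific speed on a day is expressed as a z-score against the
same day's Random probe, (mu_Random - mu_Sequence) / sd_Random, which
controls for generic (non-sequence) speedup.  Per-subject learning rates
lambda are slope summaries of day curves fit by OLS with a raw day
regressor (1..10): a linear model and a nested quadratic one compared by
likelihood-ratio test, with lambda = b_linear for the linear winner and
b_linear + b_quadratic when the quadratic model fits significantly better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from scipy.stats import t as _t_dist

from .exceptions import DegenerateInputError, InsufficientDataError
from .stats_util import bonferroni_threshold, chi2_tail

_t_sf = _t_dist.sf

__all__ = [
    "LearningRate",
    "sequence_specific_rt",
    "fit_learning_rate",
    "rt_variability",
    "bootstrap_day_correlation",
    "median_split",
]

_RSS_FLOOR = 1e-12


@dataclass(frozen=True)
class LearningRate:
    lam: float
    model: Literal["linear", "quadratic"]
    beta_linear: float
    beta_quadratic: Optional[float]
    lr_test_p: float


def _drop_missing(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[np.isfinite(x)]


def sequence_specific_rt(random_probe_rts, sequence_probe_rts) -> float:
    """Sequence-specific RT z-score (mu_R - mu_S) / sd_R for one day.

    Positive values mean faster Sequence-probe responses than Random-probe
    ones.  Missing RTs (NaN) are excluded, not imputed.
    """
    r = _drop_missing(random_probe_rts)
    s = _drop_missing(sequence_probe_rts)
    if r.size < 2 or s.size < 2:
        raise InsufficientDataError("need >= 2 non-missing RTs in each probe block")
    sd_r = r.std(ddof=1)
    if sd_r == 0.0:
        raise DegenerateInputError("Random-probe RT SD is zero; z-score undefined")
    return float((r.mean() - s.mean()) / sd_r)


def _gauss_loglik(rss: float, n: int) -> float:
    """Max Gaussian log-likelihood of an OLS fit with residual SS ``rss``."""
    rss = max(rss, _RSS_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def fit_learning_rate(values, alpha: float = 0.05) -> LearningRate:
    """Across-day learning rate lambda by linear-vs-quadratic model selection.

    Fits value = a + b*day and value = a + b*day + c*day^2 on the raw day
    regressor, compares them by a likelihood-ratio test (2 * delta-loglik
    vs chi-square with 1 df), and picks the quadratic model iff p < alpha.
    lambda = b for the linear winner, b + c for the quadratic one.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 4 or not np.isfinite(y).all():
        raise InsufficientDataError("fit_learning_rate needs >= 4 complete days")
    day = np.arange(1, n + 1, dtype=float)

    X1 = np.column_stack([np.ones(n), day])
    X2 = np.column_stack([np.ones(n), day, day**2])
    beta1, rss1 = _ols(X1, y)
    beta2, rss2 = _ols(X2, y)

    if rss1 <= _RSS_FLOOR:  # already a perfect line (includes constant series)
        return LearningRate(float(beta1[1]), "linear", float(beta1[1]), None, 1.0)

    lr_stat = max(0.0, 2.0 * (_gauss_loglik(rss2, n) - _gauss_loglik(rss1, n)))
    p = chi2_tail(lr_stat, 1)
    if p < alpha:
        return LearningRate(
            float(beta2[1] + beta2[2]), "quadratic", float(beta2[1]), float(beta2[2]), p
        )
    return LearningRate(float(beta1[1]), "linear", float(beta1[1]), None, p)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def rt_variability(probe_rts) -> float:
    """Sample standard deviation (ms) of the non-missing probe RTs."""
    x = _drop_missing(probe_rts)
    if x.size < 2:
        raise DegenerateInputError("rt_variability needs >= 2 non-missing RTs")
    return float(x.std(ddof=1))


@dataclass(frozen=True)
class DayCorrelation:
    day: int
    r: float
    boot_sd: float
    significant: bool
    p: float


def bootstrap_day_correlation(
    per_day_sd,
    lambdas,
    n_boot: int = 1000,
    n_comparisons: int = 10,
    alpha: float = 0.05,
    method: Literal["pearson", "spearman"] = "pearson",
    rng: Optional[np.random.Generator] = None,
) -> list[DayCorrelation]:
    """Correlate each day's RT variability with across-day learning rates.

    For every day, the subject-level correlation between that day's RT SD
    and lambda is computed and its sampling SD estimated by resampling
    subjects with replacement ``n_boot`` times.  Significance is a
    one-sample t-test of the bootstrap distribution against r = 0 on the
    variance-stabilizing Fisher-z scale (t = mean(z_boot) / sd(z_boot),
    df = n_subjects - 1) at the Bonferroni-corrected level
    alpha / n_comparisons; the raw-r scale is anti-conservative at this
    sample size.
    """
    sds = np.asarray(per_day_sd, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if sds.ndim != 2 or sds.shape[0] != lam.size:
        raise ValueError("per_day_sd must be subjects x days, aligned with lambdas")
    n_subj, n_days = sds.shape
    if n_subj < 5:
        raise InsufficientDataError("bootstrap_day_correlation needs >= 5 subjects")
    rng = rng or np.random.default_rng()
    thresh = bonferroni_threshold(alpha, n_comparisons)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if method == "spearman":
            from .stats_util import spearman

            return spearman(a, b)[0]
        if a.std() == 0.0 or b.std() == 0.0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    out = []
    for d in range(n_days):
        col = sds[:, d]
        if col.std() == 0.0 or lam.std() == 0.0:
            out.append(DayCorrelation(d + 1, np.nan, np.nan, False, np.nan))
            continue
        r_obs = corr(col, lam)
        boot = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(n_subj, size=n_subj)
            boot[i] = corr(col[idx], lam[idx])
        boot = boot[np.isfinite(boot)]
        if boot.size < 2 or boot.std(ddof=1) == 0.0:
            out.append(DayCorrelation(d + 1, r_obs, 0.0, False, np.nan))
            continue
        boot_sd = float(boot.std(ddof=1))
        zb = np.arctanh(np.clip(boot, -0.9999, 0.9999))
        zb_sd = float(zb.std(ddof=1))
        if zb_sd == 0.0:  # degenerate bootstrap (e.g. |r| = 1 in every resample)
            p = 0.0 if zb.mean() != 0.0 else 1.0
        else:
            t = float(zb.mean() / zb_sd)
            p = float(2.0 * _t_sf(abs(t), n_subj - 1))
        out.append(DayCorrelation(d + 1, r_obs, boot_sd, bool(p < thresh), p))
    return out


def median_split(lambdas) -> np.ndarray:
    """Split subjects into 'high' / 'low' learners at the median.

    Values strictly above the median are 'high'; values at or below it
    (including the median element itself with odd n, and every value when
    all are tied) are 'low'.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size < 2:
        raise InsufficientDataError("median_split needs >= 2 subjects")
    med = np.median(lam)
    return np.where(lam > med, "high", "low")
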