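"""Chunk-size estimation from the inter-trial autocorrelation of probe RTs.

The estimator rests on two assumptions: coupled ("bound") response plans
make successive RTs correlated, while motor/execution noise is independent
across trials.  Preprocessing drops the first sequence cycle (32 trials),
mean-imputes omitted RTs, removes the OLS linear trend and zero-means the
series.  The autocorrelation is then evaluated at lags 1..31 (the sequence
length minus one).  Each subject's Sequence-probe ACF is referred, lag by
lag, to a cross-subject null built from the same day's Random-probe ACFs
(mean mu(l) and SD sigma(l) across subjects); the chunk size is the number
of consecutive lags from lag 1 whose t statistic (rho - mu)/sigma is
significant at a Bonferroni-corrected level with rho above the null mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import DegenerateInputError, InsufficientDataError
from .stats_util import bonferroni_threshold

__all__ = [
    "N_ACF_LAGS",
    "AcfProfile",
    "AcfNull",
    "ChunkEstimate",
    "preprocess_probe",
    "acf31",
    "build_null",
    "chunk_size",
]

#: Lags of the probe-block autocorrelation: the full sequence span, 31.
N_ACF_LAGS = 31
_FIRST_CYCLE = 32


@dataclass(frozen=True)
class AcfProfile:
    rho: np.ndarray  # autocorrelation at lags 1..n_lags
    n_trials_used: int
    block_type: Optional[str] = None


@dataclass(frozen=True)
class AcfNull:
    mu: np.ndarray
    sigma: np.ndarray
    n_subjects: int


@dataclass(frozen=True)
class ChunkEstimate:
    size: int
    t_stats: np.ndarray
    alpha_corrected: float


def preprocess_probe(rts, missing_mask=None) -> np.ndarray:
    """Detrended, zero-mean probe RT series ready for autocorrelation.

    Drops the first 32 trials (the first sequence cycle, which often shows
    an exponential settling transient), replaces missing RTs with the mean
    of the retained non-missing trials, and removes the OLS linear trend
    over trial index.  Emits a warning when more than half the retained
    trials are missing, but proceeds.
    """
    x = np.asarray(rts, dtype=float).copy()
    if missing_mask is not None:
        x[np.asarray(missing_mask, dtype=bool)] = np.nan
    if x.ndim != 1 or x.size < 2 * _FIRST_CYCLE:
        raise InsufficientDataError(f"preprocess_probe needs >= {2 * _FIRST_CYCLE} trials")
    x = x[_FIRST_CYCLE:]
    missing = ~np.isfinite(x)
    n_missing = int(missing.sum())
    if n_missing == x.size:
        raise DegenerateInputError("all retained trials are missing")
    if n_missing > 0.5 * x.size:
        warnings.warn(
            f"{n_missing}/{x.size} retained trials missing; mean imputation dominates",
            RuntimeWarning,
            stacklevel=2,
        )
    x[missing] = x[~missing].mean()
    t = np.arange(x.size, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    return x - (intercept + slope * t)


def acf31(detrended, n_lags: int = N_ACF_LAGS, block_type: Optional[str] = None) -> AcfProfile:
    """Biased (1/n-normalized) autocorrelation at lags 1..n_lags.

    rho(l) = sum_t x_t x_{t+l} / sum_t x_t^2 on the (zero-meaned) input;
    the biased normalization keeps |rho| <= 1 at every lag.
    """
    x = np.asarray(detrended, dtype=float)
    if x.ndim != 1 or x.size <= 2 * n_lags:
        raise InsufficientDataError(f"acf needs more than {2 * n_lags} trials")
    x = x - x.mean()
    c0 = float(x @ x)
    if c0 == 0.0:
        raise DegenerateInputError("zero-variance series has no autocorrelation")
    full = np.correlate(x, x, mode="full")
    rho = full[x.size : x.size + n_lags] / c0
    return AcfProfile(rho=rho, n_trials_used=x.size, block_type=block_type)


def build_null(random_probe_acfs: Sequence[AcfProfile]) -> AcfNull:
    """Cross-subject null: per-lag mean and sample SD of Random-probe ACFs."""
    if len(random_probe_acfs) < 2:
        raise InsufficientDataError("null distribution needs >= 2 subjects")
    mat = np.vstack([p.rho for p in random_probe_acfs])
    return AcfNull(
        mu=mat.mean(axis=0),
        sigma=mat.std(axis=0, ddof=1),
        n_subjects=mat.shape[0],
    )


def chunk_size(
    seq_acf: AcfProfile,
    null: AcfNull,
    alpha: float = 0.05,
    n_comparisons: int = N_ACF_LAGS,
    reference: str = "t",
) -> ChunkEstimate:
    """Consecutive-significant-lag count from lag 1: the chunk-size estimate.

    t(l) = (rho(l) - mu(l)) / sigma(l) is referred two-sided to a t
    distribution with null.n_subjects - 1 df (or a standard normal with
    ``reference='z'``) at alpha / n_comparisons.  A lag counts toward the
    chunk only when it is significant *and* rho exceeds the null mean — a
    significantly negative autocorrelation is not response binding.
    """
    if null.n_subjects < 2:
        raise InsufficientDataError("null distribution needs >= 2 subjects")
    rho = seq_acf.rho
    if rho.shape != null.mu.shape:
        raise ValueError("profile and null must cover the same lags")
    if np.any(null.sigma == 0.0):
        raise DegenerateInputError("null SD is zero at some lag; t statistics undefined")
    t_stats = (rho - null.mu) / null.sigma
    corrected = bonferroni_threshold(alpha, n_comparisons)
    if reference == "t":
        p = 2.0 * _sps.t.sf(np.abs(t_stats), null.n_subjects - 1)
    elif reference == "z":
        p = 2.0 * _sps.norm.sf(np.abs(t_stats))
    else:
        raise ValueError("reference must be 't' or 'z'")
    significant = (p < corrected) & (rho > null.mu)
    size = 0
    for flag in significant:
        if not flag:
            break
        size += 1
    return ChunkEstimate(size=size, t_stats=t_stats, alpha_corrected=corrected)
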