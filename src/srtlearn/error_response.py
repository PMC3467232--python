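"""Post-error slowing via the error response function (ERF).

The ERF of a probe block is the mean reaction-time deviation from the
block mean at the six trials following each error.  Every error opens its
own lag window (windows may overlap, truncated at the block end); trials
that are themselves errors still open windows but never contribute RT
values, and missing RTs contribute nothing.  The lag-1 value serves as the
post-error slowing (PES) magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DegenerateInputError

__all__ = ["Erf", "error_response_function", "pes_magnitude"]

N_ERF_LAGS = 6


@dataclass(frozen=True)
class Erf:
    """Mean post-error RT deviation at lags 1..n; NaN where no trial contributed."""

    lag_means_ms: np.ndarray
    n_contributions: np.ndarray
    n_errors_used: int
    block_type: Optional[str] = None


def error_response_function(
    rts,
    is_error,
    block_mean_ms: float,
    n_lags: int = N_ERF_LAGS,
    block_type: Optional[str] = None,
) -> Optional[Erf]:
    """ERF of one block; ``None`` when the block contains no errors.

    ``rts`` may contain NaN for omitted responses.  Each error at position
    t lets trials t+1 .. t+n_lags contribute (rt - block_mean_ms) to the
    corresponding lag; per-lag means are taken over all contributions.
    """
    rt = np.asarray(rts, dtype=float)
    err = np.asarray(is_error, dtype=bool)
    if rt.shape != err.shape or rt.ndim != 1:
        raise ValueError("rts and is_error must be 1-D and the same length")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    error_idx = np.flatnonzero(err)
    if error_idx.size == 0:
        return None

    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=np.int64)
    n = rt.size
    contributes = np.isfinite(rt) & ~err
    dev = rt - block_mean_ms
    for t in error_idx:
        stop = min(n, t + n_lags + 1)
        for pos in range(t + 1, stop):
            if contributes[pos]:
                lag = pos - t - 1
                sums[lag] += dev[pos]
                counts[lag] += 1

    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Erf(
        lag_means_ms=means,
        n_contributions=counts,
        n_errors_used=int(error_idx.size),
        block_type=block_type,
    )


def pes_magnitude(erf: Erf) -> float:
    """Post-error slowing index: the ERF's lag-1 mean deviation (ms)."""
    if erf.lag_means_ms.size == 0 or not np.isfinite(erf.lag_means_ms[0]):
        raise DegenerateInputError("ERF has no lag-1 contributions; PES undefined")
    return float(erf.lag_means_ms[0])
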