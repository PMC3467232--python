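"""Hand-implemented inferential statistics used throughout the pipeline.

One-sample t, Spearman rank correlation, Bonferroni adjustment, and one-
and two-way repeated-measures (within-subject) ANOVA.  The statistics are
computed from their definitional sums of squares; `scipy.stats` supplies
only the t/F/chi-square tail functions and midrank assignment.

No sphericity correction is applied by default: F ratios are referred to
the uncorrected within-subject degrees of freedom.  A Greenhouse-Geisser
flag is available on the one-way ANOVA for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .exceptions import DegenerateInputError, InsufficientDataError

__all__ = [
    "RmAnovaResult",
    "one_sample_t",
    "paired_t",
    "spearman",
    "bonferroni_threshold",
    "bonferroni_adjust",
    "chi2_tail",
    "rm_anova_oneway",
    "rm_anova_twoway",
]


@dataclass(frozen=True)
class RmAnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float]:
    """Classical one-sample t-test of ``mean(values) == mu0``, two-sided."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("one_sample_t needs n >= 2")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("one_sample_t undefined for zero-variance input")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * _sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test, i.e. a one-sample t on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired_t requires equal-length samples")
    return one_sample_t(x - y, 0.0)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties; t-approximation p.

    Computed as the Pearson correlation of the rank vectors, which handles
    ties correctly without the shortcut d^2 formula.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise InsufficientDataError("spearman needs two equal vectors of length >= 4")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("spearman undefined for constant input")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return rho, float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison alpha for a family of ``m`` tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bonferroni_adjust(p, m: int) -> np.ndarray:
    """Adjusted p-values min(1, p*m); monotone in m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def chi2_tail(stat: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    return float(_sps.chi2.sf(stat, df))


def rm_anova_oneway(data, effect: str = "condition", gg_correction: bool = False) -> RmAnovaResult:
    """One-way within-subject ANOVA on a subjects x conditions matrix.

    Decomposes total SS into subject, condition, and subject-by-condition
    (error) components; F = MS_condition / MS_error with dfs (k-1) and
    (n-1)(k-1).  With ``gg_correction`` the dfs (not F) are scaled by the
    Greenhouse-Geisser epsilon estimated from the condition covariance.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("one-way rm_anova expects a 2-D subjects x conditions matrix")
    if not np.isfinite(y).all():
        raise ValueError("rm_anova requires complete, balanced data")
    n, k = y.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 conditions")
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_num, df_den = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df_den
    if ms_err <= 0:
        raise DegenerateInputError("zero error variance in rm_anova")
    F = (ss_cond / df_num) / ms_err
    eps = 1.0
    if gg_correction:
        S = np.cov(y, rowvar=False, ddof=1)
        dbar = S.diagonal().mean()
        eps = (k * (dbar - S.mean())) ** 2 / (
            (k - 1) * (np.sum(S * S) - 2 * k * np.sum(S.mean(axis=0) ** 2) + k * k * S.mean() ** 2)
        )
        eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    p = float(_sps.f.sf(F, df_num * eps, df_den * eps))
    return RmAnovaResult(effect, float(F), df_num, df_den, p)


def rm_anova_twoway(data, factor_a: str = "A", factor_b: str = "B") -> list[RmAnovaResult]:
    """Two-way fully within-subject ANOVA on a subjects x A x B array.

    Each effect is tested against its own subject-by-effect interaction:
    A against subj x A, B against subj x B, and A x B against subj x A x B.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("two-way rm_anova expects a 3-D subjects x A x B array")
    if not np.isfinite(y).all():
        raise ValueError("rm_anova requires complete, balanced data")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise InsufficientDataError("need >= 2 levels on every factor")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))            # subject
    m_a = y.mean(axis=(0, 2))            # factor A
    m_b = y.mean(axis=(0, 1))            # factor B
    m_sa = y.mean(axis=2)                # subject x A
    m_sb = y.mean(axis=1)                # subject x B
    m_ab = y.mean(axis=0)                # A x B

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_sab = ss_total - ss_a - ss_b - ss_s - ss_sa - ss_sb - ss_ab

    out = []
    for name, ss_eff, df_eff, ss_err, df_err in (
        (factor_a, ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        (factor_b, ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        (f"{factor_a} x {factor_b}", ss_ab, (a - 1) * (b - 1), ss_sab, (n - 1) * (a - 1) * (b - 1)),
    ):
        ms_err = ss_err / df_err
        if ms_err <= 0:
            raise DegenerateInputError(f"zero error variance for effect {name}")
        F = (ss_eff / df_eff) / ms_err
        out.append(RmAnovaResult(name, float(F), df_eff, df_err, float(_sps.f.sf(F, df_eff, df_err))))
    return out
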