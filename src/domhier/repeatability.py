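"""Correlation and repeatability statistics.

Two estimators carry all the stability analyses downstream:

* Pearson product-moment correlation with a Fisher-z 95% confidence
  interval, ``atanh(r) +/- z * 1/sqrt(n - 3)`` back-transformed;
* the one-way ANOVA intraclass correlation (repeatability): with
  subjects as the grouping factor and k repeats each,
  ``s2_A = (MS_A - MS_W) / k`` and ``ICC = s2_A / (s2_A + MS_W)``.

Negative ICC estimates are reported as-is rather than truncated at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CorrelationResult", "ICCResult", "fisher_ci", "pearson_with_ci", "icc_oneway"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    method: str = "fisher-z"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    n_subjects: int
    k_measures: int


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    ``tanh(atanh(r) +/- z * 1/sqrt(n - 3))`` with the normal quantile z
    for the requested level.  Requires ``|r| < 1`` and ``n >= 4``.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"r must be strictly inside (-1, 1), got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def pearson_with_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval.

    Requires paired complete vectors of length >= 4 (the Fisher standard
    error ``1/sqrt(n-3)`` needs n > 3).  A degenerate perfect
    correlation returns the interval (r, r).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed; drop incomplete pairs first")
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4 paired observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return CorrelationResult(r=r, n=n, ci_low=r, ci_high=r)
    lo, hi = fisher_ci(r, n, level)
    return CorrelationResult(r=r, n=n, ci_low=lo, ci_high=hi)


def icc_oneway(measures) -> ICCResult:
    """One-way ANOVA intraclass correlation for a subjects x repeats matrix.

    Assumes a balanced design (every subject measured k times, no
    missing cells).  ICC is the proportion of variance attributable to
    differences among subjects; it can be negative when within-subject
    scatter exceeds between-subject scatter, and such estimates are
    returned untruncated.
    """
    m = np.asarray(measures, dtype=float)
    if m.ndim != 2:
        raise ValueError("measures must be a 2-D subjects x repeats matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 repeats, got {n} x {k}")
    if np.isnan(m).any():
        raise ValueError("missing cells are not allowed in the balanced one-way ICC")
    grand = m.mean()
    if np.allclose(m, grand):
        raise ValueError("constant matrix: zero total variance, ICC undefined")
    row_means = m.mean(axis=1)
    ss_between = k * float(((row_means - grand) ** 2).sum())
    ss_within = float(((m - row_means[:, None]) ** 2).sum())
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    s2_a = (ms_between - ms_within) / k
    icc = s2_a / (s2_a + ms_within)
    return ICCResult(icc=float(icc), n_subjects=n, k_measures=k)
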