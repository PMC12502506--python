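"""Hydrological trend analysis: Theil-Sen slope, Mann-Kendall test, CV.

The Theil-Sen estimator is the median of all pairwise slopes
(y_j - y_i)/(t_j - t_i), i < j, robust to outliers up to a ~29% breakdown
point.  The Mann-Kendall test uses S = sum_{i<j} sgn(y_j - y_i) with
tie-corrected variance and a continuity-corrected normal approximation,
two-sided.  The coefficient of variation uses the sample (n-1) standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import ValidationError


@dataclass
class TrendResult:
    slope: float  # Theil-Sen, units of y per unit t
    intercept: float  # median(y - slope * t)
    s: int  # Mann-Kendall S
    var_s: float  # tie-corrected Var(S)
    z: float  # continuity-corrected normal deviate
    p_value: float  # two-sided
    n: int

    @property
    def stars(self) -> str:
        """Significance stars: *, **, *** at 0.05 / 0.01 / 0.001."""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "NS"


@dataclass
class SeriesSummary:
    mean: float
    sd: float  # sample sd, n-1 denominator
    cv: float  # sd / mean
    n: int


def theil_sen(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Median of all pairwise slopes, with intercept median(y - slope*t).

    Requires n >= 3 and strictly increasing time points.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("t and y must be 1-d arrays of equal length")
    n = len(t)
    if n < 3:
        raise ValidationError(f"need at least 3 points, got {n}")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("time points must be strictly increasing")
    i, j = np.triu_indices(n, 1)
    slopes = (y[j] - y[i]) / (t[j] - t[i])
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * t))
    return slope, intercept


def mann_kendall(y: np.ndarray) -> tuple[int, float, float, float]:
    """Mann-Kendall monotonic trend test.

    Returns (S, Var(S), Z, p).  sgn(0) = 0, so tied pairs do not count in
    S; tie groups enter the variance correction
    Var(S) = [n(n-1)(2n+5) - sum_k t_k(t_k-1)(2t_k+5)] / 18.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValidationError("need a 1-d series of length >= 3")
    n = len(y)
    i, j = np.triu_indices(n, 1)
    s = int(np.sign(y[j] - y[i]).sum())
    _, tie_counts = np.unique(y, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values tied
        return s, float(var_s), 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2 * stats.norm.sf(abs(z))
    return s, float(var_s), float(z), float(min(p, 1.0))


def trend_analysis(t: np.ndarray, y: np.ndarray) -> TrendResult:
    """Theil-Sen slope plus Mann-Kendall significance for one series."""
    slope, intercept = theil_sen(t, y)
    s, var_s, z, p = mann_kendall(np.asarray(y, dtype=float))
    return TrendResult(slope, intercept, s, var_s, z, p, len(np.asarray(y)))


def coefficient_of_variation(y: np.ndarray) -> SeriesSummary:
    """CV = sample sd / mean; rejects non-positive means, for which the
    ratio is not interpretable."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValidationError("need a 1-d series of length >= 2")
    mean = float(y.mean())
    if mean <= 0:
        raise ValidationError(f"CV undefined for non-positive mean ({mean:.4g})")
    sd = float(y.std(ddof=1))
    return SeriesSummary(mean=mean, sd=sd, cv=sd / mean, n=len(y))
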