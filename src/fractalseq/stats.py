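"""Simple-regression and skewness primitives.

Only the two statistics the analyses need: ordinary least squares of one
response on one predictor, summarized by slope, intercept, R-squared and
adjusted R-squared (one predictor: 1 - (1-R^2)(n-1)/(n-2)); and sample
skewness in the adjusted Fisher-Pearson form g1 * sqrt(n(n-1))/(n-2), the
convention spreadsheet SKEW functions use.  No p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    n: int


@dataclass(frozen=True)
class SkewnessResult:
    skewness: float
    n: int
    mean: float
    sd: float


def ols_fit(x, y) -> RegressionResult:
    """Least-squares line of y on x with R^2 and adjusted R^2.

    Requires at least 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D vectors, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points for a regression, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor has zero variance")
    if np.ptp(y) == 0.0:
        # a flat response: the line y = mean(y) explains nothing, R^2 = 0
        adj = 1.0 - (n - 1) / (n - 2)
        return RegressionResult(
            slope=0.0, intercept=float(np.mean(y)), r2=0.0, adjusted_r2=adj, n=int(n),
        )
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue) ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=r2, adjusted_r2=float(adj), n=int(n),
    )


def skewness(values, adjusted: bool = True) -> SkewnessResult:
    """Sample skewness of a vector (n >= 3, non-constant).

    ``adjusted=True`` gives the adjusted Fisher-Pearson coefficient;
    ``adjusted=False`` the plain moment ratio g1 = m3 / m2^{3/2}.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D vector with at least 3 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in skewness input")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: skewness undefined")
    g = float(sps.skew(v, bias=not adjusted))
    return SkewnessResult(skewness=g, n=int(v.size), mean=float(np.mean(v)), sd=sd)
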