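"""Higuchi fractal dimension of a 1-D numeric series.

The estimator measures the apparent curve length of the series at integer
lags k = 1..maxK:

    L(k) = [ sum_{i=k+1..N} |Int(i) - Int(i-k)| ] * (1/k^2) * (N-1)/(N-k)

i.e. the sum of absolute differences over all index pairs separated by k,
with the first k wrapped differences removed as end effects, normalized by
the pair count and by Higuchi's 1/k^2 calibration so that the maximum
attainable dimension of a 1-D signal is the topological value 2.  For a
fractal series, log L(k) against log(1/k) is a straight line whose slope
is the fractal dimension: values near 2 indicate a rough, information-rich
signal, values near 1 a smooth one (an exact ramp gives exactly 1).

The k-grid is the full integer range 1..maxK (no geometric spacing), and
the fit is ordinary least squares with an intercept on natural-log axes;
the slope is invariant to the logarithm base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .encoding import NumericSeries

DEFAULT_MAX_K = 7


class DegenerateSeriesError(ValueError):
    """A series whose curve length vanishes at some lag (e.g. a constant)."""


@dataclass(frozen=True)
class CurveLengths:
    """Normalized curve lengths L(1..maxK) for a series of length N."""

    max_k: int
    lengths: np.ndarray
    n: int


@dataclass(frozen=True)
class FractalResult:
    """Fitted fractal dimension with the regression intercept and raw L(k)."""

    fd: float
    intercept: float
    curve_lengths: CurveLengths


def _as_array(series: Union[NumericSeries, np.ndarray, list]) -> np.ndarray:
    if isinstance(series, NumericSeries):
        return series.values
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be 1-D")
    return arr


def curve_lengths(
    series: Union[NumericSeries, np.ndarray, list],
    max_k: int = DEFAULT_MAX_K,
) -> CurveLengths:
    """Normalized curve length at each lag k = 1..max_k.

    Requires ``2 <= max_k <= N - 1``.
    """
    x = _as_array(series)
    n = x.size
    if max_k < 2:
        raise ValueError(f"max_k must be at least 2, got {max_k}")
    if max_k >= n:
        raise ValueError(f"max_k must be smaller than the series length ({max_k} >= {n})")
    out = np.empty(max_k, dtype=float)
    for k in range(1, max_k + 1):
        diffs = np.abs(x[k:] - x[:-k])
        out[k - 1] = diffs.sum() / (k * k) * (n - 1) / (n - k)
    return CurveLengths(max_k=max_k, lengths=out, n=n)


def higuchi_fd(
    series: Union[NumericSeries, np.ndarray, list],
    max_k: int = DEFAULT_MAX_K,
) -> FractalResult:
    """Fractal dimension as the slope of log L(k) versus log(1/k).

    Raises :class:`DegenerateSeriesError` when any L(k) is zero (constant
    or otherwise degenerate series): the dimension is then undefined.
    """
    cl = curve_lengths(series, max_k)
    if np.any(cl.lengths <= 0.0):
        raise DegenerateSeriesError("degenerate series: fractal dimension undefined")
    k = np.arange(1, max_k + 1, dtype=float)
    log_inv_k = np.log(1.0 / k)
    log_l = np.log(cl.lengths)
    # design matrix [1, log(1/k)]; slope coefficient is the dimension
    design = np.column_stack([np.ones_like(log_inv_k), log_inv_k])
    coef, *_ = np.linalg.lstsq(design, log_l, rcond=None)
    return FractalResult(fd=float(coef[1]), intercept=float(coef[0]), curve_lengths=cl)
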