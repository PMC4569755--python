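"""Passing-Bablok method-comparison regression.

Used to put 25(OH)D measured by a one-step immunoassay and by LC-MS/MS
on a common scale before pooling or cross-validating cohorts.  The
estimator is the classic one for structural method comparison: the
slope is the shifted median of all pairwise slopes, which makes it
robust to outliers and symmetric in the measurement errors of both
methods, unlike ordinary least squares.

Conventions (the classic 1983 formulation):

* pairwise slopes exactly equal to -1 are discarded;
* tied pairs (dx == 0 and dy == 0) are discarded;
* dx == 0 with dy != 0 contributes a signed infinite slope, ranked at
  the extremes;
* the median is offset by K, the number of slopes below -1, which makes
  the estimate invariant to swapping the axes up to inversion;
* confidence bounds come from the rank-based normal approximation with
  w = z_{(1+conf)/2} * sqrt(n(n-1)(2n+5)/18).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["CalibrationLine", "pb_fit", "pb_apply"]


@dataclass(frozen=True)
class CalibrationLine:
    """A fitted method-comparison line: method_b = intercept + slope * method_a.

    ``scale`` records whether the line was fitted on original (nmol/L)
    or square-root transformed values; ``pb_apply`` refuses to apply a
    line to values declared on the other scale.
    """

    intercept: float
    slope: float
    ci_intercept: tuple[float, float] = (float("nan"), float("nan"))
    ci_slope: tuple[float, float] = (float("nan"), float("nan"))
    scale: str = "original"
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.scale not in ("original", "sqrt"):
            raise ValueError(f"scale must be 'original' or 'sqrt', got {self.scale!r}")


#: The published immunoassay-vs-LC-MS/MS comparison line (125 serums,
#: original nmol/L scale): architect = 8.71 + 0.86 * lcms.
PUBLISHED_CALIBRATION = CalibrationLine(
    intercept=8.71,
    slope=0.86,
    ci_intercept=(3.31, 13.55),
    ci_slope=(0.76, 0.95),
    scale="original",
    n_pairs=125,
)


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    # vertical pairs: signed infinity; coincident pairs: drop (nan)
    s = np.where(dx == 0, np.where(dy > 0, np.inf, np.where(dy < 0, -np.inf, np.nan)), s)
    s = s[~np.isnan(s)]
    return s[s != -1.0]


def pb_fit(x, y, conf: float = 0.95, scale: str = "original") -> CalibrationLine:
    """Fit a Passing-Bablok line y = intercept + slope * x.

    Parameters
    ----------
    x, y
        Paired measurements of the same samples by two methods
        (method A on x, method B on y); at least 3 pairs, x not constant.
    conf
        Confidence level for the rank-based intervals.
    scale
        Scale tag recorded on the returned line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.all(x == x[0]):
        raise ValueError("all x values identical; slope undefined")
    slopes = np.sort(_pairwise_slopes(x, y))
    N = len(slopes)
    if N == 0:
        raise ValueError("no valid pairwise slopes")
    K = int(np.sum(slopes < -1.0))
    slope = _offset_median(slopes, K)
    if not np.isfinite(slope):
        raise ValueError("Passing-Bablok slope is not finite; check the pairing")

    z = norm.ppf((1.0 + conf) / 2.0)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((N - w) / 2.0))
    m2 = N - m1 + 1
    lo = slopes[np.clip(m1 + K - 1, 0, N - 1)]
    hi = slopes[np.clip(m2 + K - 1, 0, N - 1)]

    intercept = float(np.median(y - slope * x))
    # higher slope bound gives the lower intercept bound and vice versa
    a_lo = float(np.median(y - hi * x)) if np.isfinite(hi) else float("nan")
    a_hi = float(np.median(y - lo * x)) if np.isfinite(lo) else float("nan")
    return CalibrationLine(
        intercept=intercept,
        slope=float(slope),
        ci_intercept=(a_lo, a_hi),
        ci_slope=(float(lo), float(hi)),
        scale=scale,
        n_pairs=n,
    )


def _offset_median(sorted_slopes: np.ndarray, offset: int) -> float:
    N = len(sorted_slopes)
    if N % 2 == 1:
        idx = (N + 1) // 2 + offset - 1
        return float(sorted_slopes[np.clip(idx, 0, N - 1)])
    i1 = np.clip(N // 2 + offset - 1, 0, N - 1)
    i2 = np.clip(N // 2 + offset, 0, N - 1)
    return float(0.5 * (sorted_slopes[i1] + sorted_slopes[i2]))


def pb_apply(line: CalibrationLine, values, direction: str = "a_to_b", *,
             scale: str | None = None):
    """Map values across the calibration line.

    ``a_to_b`` applies ``v -> intercept + slope * v``; ``b_to_a`` its
    inverse.  If ``scale`` is given it must match the line's scale tag —
    a sqrt-scale line must be applied to sqrt-transformed values.
    """
    if scale is not None and scale != line.scale:
        raise ValueError(
            f"scale mismatch: line is on the {line.scale!r} scale, "
            f"values declared {scale!r}"
        )
    if line.slope == 0:
        raise ValueError("cannot apply a line with zero slope")
    v = np.asarray(values, dtype=float)
    if direction == "a_to_b":
        out = line.intercept + line.slope * v
    elif direction == "b_to_a":
        out = (v - line.intercept) / line.slope
    else:
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    return float(out) if np.isscalar(values) else out
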