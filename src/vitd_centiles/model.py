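"""Closed-form prediction math for the seasonal 25(OH)D centile model.

The model is an ordinary linear regression fitted on square-root
transformed serum 25(OH)D (nmol/L).  The mean on the sqrt scale is a
linear combination of ten regressors: an intercept, annual and
semi-annual sine/cosine harmonics of the measurement day, an inverse
square-root transform of BMI and its square, a one-sided quadratic
low-BMI term for men, and female-specific copies of the annual
harmonics.  Residuals on the sqrt scale are treated as homoscedastic
Gaussian with standard deviation ``sigma_eps``, so any centile of the
25(OH)D distribution follows in closed form and any measurement can be
inverted into a population quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ModelCoefficients",
    "PUBLISHED_MODEL",
    "TERM_NAMES",
    "bmi_transform",
    "day_of_year",
    "day_to_month_day",
    "seasonal_basis",
    "design_vector",
    "design_matrix",
    "mean_sqrt",
    "centile",
    "quantile_of",
    "extremum_days",
]

#: Regressor names, in the fixed layout of the fitted equation.
TERM_NAMES = (
    "intercept",
    "sin1",
    "cos1",
    "sin2",
    "cos2",
    "tbmi",
    "tbmi_sq",
    "male_lowbmi",
    "f_sin1",
    "f_cos1",
)

# Cumulative day counts for a non-leap year, used for date <-> day-of-year.
_MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_CUM_DAYS = tuple(int(x) for x in np.cumsum((0,) + _MONTH_DAYS))


@dataclass(frozen=True)
class ModelCoefficients:
    """The fitted model: ten regression coefficients plus residual SD.

    Parameters
    ----------
    beta
        Coefficients in the order of :data:`TERM_NAMES`
        (sqrt(nmol/L) per unit regressor).
    sigma_eps
        Residual standard deviation on the sqrt scale, > 0.
    provenance
        Free-text label tracking where the coefficients came from.
    """

    beta: tuple[float, ...]
    sigma_eps: float
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.beta) != 10:
            raise ValueError(f"expected 10 coefficients, got {len(self.beta)}")
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        if not (self.sigma_eps > 0):
            raise ValueError(f"sigma_eps must be > 0, got {self.sigma_eps}")

    @property
    def beta_array(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)


#: Reference coefficients as published, fitted on 4,912 Swiss adults
#: (35-65 y, BMI 18-40, no vitamin D supplementation), 25(OH)D by LC-MS/MS.
PUBLISHED_MODEL = ModelCoefficients(
    beta=(-2.754, -1.077, -0.756, 0.188, 0.025, -81.08, -165.6, -1174.0, 0.218, 0.164),
    sigma_eps=1.36,
    provenance="published-2015",
)


def bmi_transform(bmi: float) -> float:
    """Inverse square-root transform t(x) = -1/sqrt(x) applied to BMI.

    Strictly increasing and always negative for positive BMI; damps the
    leverage of very large BMI values.
    """
    bmi = float(bmi)
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    return -1.0 / math.sqrt(bmi)


def day_of_year(month: int, day_of_month: int) -> int:
    """Map a calendar date to its non-leap day-of-year index (1..365).

    Feb 29 is accepted and assigned index 60 (the model has no 366-day
    mode); all later dates use their non-leap index.
    """
    month = int(month)
    dom = int(day_of_month)
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    limit = _MONTH_DAYS[month - 1] + (1 if month == 2 else 0)
    if not 1 <= dom <= limit:
        raise ValueError(f"invalid day {dom} for month {month}")
    if month == 2 and dom == 29:
        return 60
    return _CUM_DAYS[month - 1] + dom


def day_to_month_day(day: int) -> tuple[int, int]:
    """Inverse of :func:`day_of_year`: day index -> (month, day-of-month)."""
    day = int(day)
    if not 1 <= day <= 365:
        raise ValueError(f"day must be in 1..365, got {day}")
    month = int(np.searchsorted(_CUM_DAYS, day, side="left"))
    return month, day - _CUM_DAYS[month - 1]


def seasonal_basis(day):
    """Annual and semi-annual harmonics of the measurement day.

    Returns ``(s1, c1, s2, c2)`` with ``s1 = sin(2*pi*(day-1)/365)`` etc.
    The second harmonic lets the time from trough to peak differ from
    six months.  Accepts a scalar or array of integer days in 1..365.
    """
    d = np.asarray(day)
    if np.any(d < 1) or np.any(d > 365):
        raise ValueError("day must lie in 1..365")
    angle = 2.0 * np.pi * (d - 1) / 365.0
    return np.sin(angle), np.cos(angle), np.sin(2 * angle), np.cos(2 * angle)


def _validate_sex(sex: str) -> str:
    s = str(sex).upper()
    if s in ("M", "MALE"):
        return "M"
    if s in ("F", "FEMALE"):
        return "F"
    raise ValueError(f"sex must be male ('M') or female ('F'), got {sex!r}")


def design_vector(sex: str, bmi: float, day: int) -> np.ndarray:
    """Build the 10-term regressor vector for one observation.

    Layout follows :data:`TERM_NAMES`.  The ``male_lowbmi`` term is
    ``(t(BMI) - t(25))**2`` for men with BMI strictly below 25 and zero
    otherwise; it is continuous (with continuous first difference) at
    BMI 25, so predictions have no jump there.  The female harmonic
    copies are zero for men.
    """
    s = _validate_sex(sex)
    tb = bmi_transform(bmi)
    s1, c1, s2, c2 = seasonal_basis(int(day))
    male = s == "M"
    lowbmi = (tb - bmi_transform(25.0)) ** 2 if (male and bmi < 25) else 0.0
    female = 0.0 if male else 1.0
    return np.array(
        [1.0, s1, c1, s2, c2, tb, tb * tb, lowbmi, female * s1, female * c1]
    )


def design_matrix(sex, bmi, day) -> np.ndarray:
    """Vectorised :func:`design_vector` for arrays of covariates.

    ``sex`` is an array of 'M'/'F' codes; returns an (n, 10) matrix.
    """
    sex = np.asarray(sex, dtype=object)
    bmi = np.asarray(bmi, dtype=float)
    day = np.asarray(day)
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    male = np.array([_validate_sex(s) == "M" for s in sex.ravel()]).reshape(sex.shape)
    tb = -1.0 / np.sqrt(bmi)
    s1, c1, s2, c2 = seasonal_basis(day)
    t25 = -1.0 / math.sqrt(25.0)
    lowbmi = np.where(male & (bmi < 25), (tb - t25) ** 2, 0.0)
    female = (~male).astype(float)
    n = bmi.size
    X = np.empty((n, 10))
    X[:, 0] = 1.0
    X[:, 1] = np.broadcast_to(s1, (n,))
    X[:, 2] = np.broadcast_to(c1, (n,))
    X[:, 3] = np.broadcast_to(s2, (n,))
    X[:, 4] = np.broadcast_to(c2, (n,))
    X[:, 5] = tb
    X[:, 6] = tb * tb
    X[:, 7] = lowbmi
    X[:, 8] = female * np.broadcast_to(s1, (n,))
    X[:, 9] = female * np.broadcast_to(c1, (n,))
    return X


def mean_sqrt(model: ModelCoefficients, sex: str, bmi: float, day: int) -> float:
    """Fitted mean of sqrt(25(OH)D) for the given covariates."""
    return float(design_vector(sex, bmi, day) @ model.beta_array)


def centile(
    model: ModelCoefficients, sex: str, bmi: float, day: int, alpha: float
) -> float:
    """The alpha centile of 25(OH)D (nmol/L) for the given covariates.

    Computed as ``(yhat + z_alpha * sigma_eps)**2`` on the sqrt scale.
    A negative pre-square value (possible only at extreme alpha) is
    clamped at 0 with a warning: squaring a negative would silently
    break monotonicity in alpha.
    """
    alpha = float(alpha)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be a probability in (0, 1), got {alpha}")
    y = mean_sqrt(model, sex, bmi, day) + norm.ppf(alpha) * model.sigma_eps
    if y < 0:
        warnings.warn(
            f"centile at alpha={alpha} clamped to 0 (sqrt-scale value {y:.3f} < 0)",
            RuntimeWarning,
            stacklevel=2,
        )
        y = 0.0
    return y * y


def quantile_of(
    model: ModelCoefficients, sex: str, bmi: float, day: int, value: float
) -> float:
    """Population quantile of a measured 25(OH)D value (nmol/L).

    Returns ``Phi((sqrt(value) - yhat) / sigma_eps)``; the exact inverse
    of :func:`centile` wherever no clamping occurred.
    """
    value = float(value)
    if value < 0:
        raise ValueError(f"25(OH)D value must be >= 0, got {value}")
    z = (math.sqrt(value) - mean_sqrt(model, sex, bmi, day)) / model.sigma_eps
    return float(norm.cdf(z))


def extremum_days(model: ModelCoefficients, sex: str, bmi: float = 25.0):
    """Integer days of minimal and maximal predicted mean over the year.

    The BMI terms do not vary with day, so the result is independent of
    BMI; ties are broken toward the smallest day index.
    """
    days = np.arange(1, 366)
    X = design_matrix(np.repeat(_validate_sex(sex), 365), np.full(365, float(bmi)), days)
    yhat = X @ model.beta_array
    return int(days[np.argmin(yhat)]), int(days[np.argmax(yhat)])
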