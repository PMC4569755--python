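"""Synthetic cohorts with the statistical structure the model assumes.

The generator draws covariates resembling a Swiss adult population
cohort (about 49.3% male; BMI mean 25.61, SD 4.12, truncated to
[18, 40]; age mean 49.8, SD 8.5, truncated to [35, 65]) and then
simulates 25(OH)D by adding Gaussian noise (sigma_eps on the sqrt
scale) to the model mean and squaring.  A configurable fraction of
rows (default 3.9%) is flagged as supplemented with an additive
sqrt-scale shift, so that the inclusion filters have something to
exclude.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .calibration import CalibrationLine
from .model import PUBLISHED_MODEL, ModelCoefficients, design_matrix

__all__ = ["CohortSpec", "generate_cohort", "generate_paired_measurements",
           "apply_inclusion_criteria"]

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_STARTS = np.concatenate([[0], np.cumsum(_MONTH_DAYS)[:-1]])

# Default supplemented-vs-not sqrt-scale mean offset, approximately
# sqrt(66.05) - sqrt(47.58) from the contrast between supplemented and
# unsupplemented participants in the source population.
DEFAULT_SUPPLEMENT_SHIFT = 1.23


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort draw."""

    n: int = 5000
    p_male: float = 0.493
    bmi_mean: float = 25.61
    bmi_sd: float = 4.12
    bmi_range: tuple[float, float] = (18.0, 40.0)
    age_mean: float = 49.8
    age_sd: float = 8.5
    age_range: tuple[float, float] = (35.0, 65.0)
    day_weights: tuple[float, ...] | None = None  # 12 monthly weights; uniform default
    model: ModelCoefficients = PUBLISHED_MODEL
    supplement_fraction: float = 0.039
    supplement_shift: float = DEFAULT_SUPPLEMENT_SHIFT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("p_male", "supplement_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("bmi_range", "age_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds must be ordered, got {(lo, hi)}")
        if self.bmi_sd <= 0 or self.age_sd <= 0:
            raise ValueError("bmi_sd and age_sd must be positive")
        if self.day_weights is not None:
            w = np.asarray(self.day_weights, dtype=float)
            if w.shape != (12,) or np.any(w < 0) or not np.any(w > 0):
                raise ValueError(
                    "day_weights must be 12 nonnegative values, not all zero")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Truncated normal on [lo, hi] whose *truncated* mean equals ``mean``.

    Asymmetric truncation shifts the mean of a plain truncated normal,
    so the location parameter is solved for numerically; the generated
    sample moments then match the stated cohort moments.
    """
    from scipy.optimize import brentq

    def truncated_mean(loc):
        return truncnorm.mean((lo - loc) / sd, (hi - loc) / sd, loc=loc, scale=sd)

    loc = brentq(lambda m: truncated_mean(m) - mean, lo - 2 * sd, hi + 2 * sd,
                 xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort under the spec's data-generating model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    male = rng.random(n) < spec.p_male
    sex = np.where(male, "M", "F")
    bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, *spec.bmi_range, n)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range, n)

    w = (np.ones(12) if spec.day_weights is None
         else np.asarray(spec.day_weights, dtype=float))
    month = rng.choice(12, size=n, p=w / w.sum())
    day = _MONTH_STARTS[month] + rng.integers(1, _MONTH_DAYS[month] + 1)

    X = design_matrix(sex, bmi, day)
    sqrt_mean = X @ spec.model.beta_array
    supplemented = rng.random(n) < spec.supplement_fraction
    sqrt_v = (sqrt_mean
              + rng.normal(0.0, spec.model.sigma_eps, n)
              + np.where(supplemented, spec.supplement_shift, 0.0))
    vitd = np.clip(sqrt_v, 0.0, None) ** 2

    return pd.DataFrame({
        "sex": sex,
        "age": age,
        "bmi": bmi,
        "day": day.astype(int),
        "vitd": vitd,
        "supplemented": supplemented,
    })


def generate_paired_measurements(
    n: int,
    line: CalibrationLine,
    noise_sd: float,
    seed: int = 0,
    true_range: tuple[float, float] = (15.0, 120.0),
) -> pd.DataFrame:
    """Paired two-method measurements for calibration testing.

    Latent true concentrations are uniform over ``true_range``; method A
    observes truth plus noise, method B observes the line applied to
    truth plus noise (independent errors on both axes, as the estimator
    assumes).
    """
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    truth = rng.uniform(*true_range, n)
    a = truth + rng.normal(0.0, noise_sd, n)
    b = line.intercept + line.slope * truth + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({
        "sample_id": np.arange(1, n + 1),
        "method_a": a,
        "method_b": b,
    })


def apply_inclusion_criteria(
    cohort: pd.DataFrame,
    age_range: tuple[float, float] = (35.0, 65.0),
    bmi_range: tuple[float, float] = (18.0, 40.0),
    keep_supplemented: bool = False,
):
    """Apply the study inclusion filters; returns (kept rows, exclusion log).

    Keeps rows with age and BMI inside the closed intervals and, unless
    ``keep_supplemented``, drops rows flagged as supplemented.  The log
    counts rows violating each criterion (a row can appear under several
    reasons) plus totals.
    """
    for col in ("age", "bmi"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    age_bad = ~cohort["age"].between(*age_range)
    bmi_bad = ~cohort["bmi"].between(*bmi_range)
    if not keep_supplemented and "supplemented" in cohort.columns:
        supp_bad = cohort["supplemented"].fillna(False).astype(bool)
    else:
        supp_bad = pd.Series(False, index=cohort.index)
    excluded = age_bad | bmi_bad | supp_bad
    kept = cohort.loc[~excluded].copy()
    log = {
        "age": int(age_bad.sum()),
        "bmi": int(bmi_bad.sum()),
        "supplemented": int(supp_bad.sum()),
        "excluded": int(excluded.sum()),
        "kept": int(len(kept)),
        "input": int(len(cohort)),
    }
    return kept, log
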