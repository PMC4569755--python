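"""Refitting the seasonal centile regression and BIC model comparison.

Candidate models are subsets of named term groups (harmonics, BMI
transforms, sex interactions, age ...), each expanding to one or more
design columns.  Fits are ordinary least squares on sqrt(25(OH)D);
``sigma_eps`` uses the unbiased denominator (n - k).  BIC is computed
under the Gaussian profile-likelihood convention, dropping additive
constants, with the variance parameter counted in k — only BIC
differences are consumed, so these conventions cancel within a
comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr

from .model import ModelCoefficients, TERM_NAMES, design_matrix

__all__ = ["CandidateSpec", "FitResult", "EQ1_TERMS", "default_candidates",
           "build_design", "fit", "bic", "select_model"]

logger = logging.getLogger(__name__)

# term group -> columns of the full Eq.-style design, by name
_TERM_COLUMNS = {
    "harmonics1": ["sin1", "cos1"],
    "harmonics2": ["sin2", "cos2"],
    "tbmi": ["tbmi"],
    "tbmi_sq": ["tbmi_sq"],
    "male_lowbmi": ["male_lowbmi"],
    "sex_harmonics1": ["f_sin1", "f_cos1"],
    "sex": ["female"],
    "age": ["age"],
    "age_sex": ["age_x_female"],
    "age_tbmi": ["age_x_tbmi"],
}

#: Term groups of the published model (besides the always-on intercept).
EQ1_TERMS = ("harmonics1", "harmonics2", "tbmi", "tbmi_sq",
             "male_lowbmi", "sex_harmonics1")


@dataclass(frozen=True)
class CandidateSpec:
    """A candidate model: a label and a set of term groups.

    The intercept is always included and is not listed.
    """

    label: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in _TERM_COLUMNS]
        if unknown:
            raise ValueError(f"unknown terms {unknown}; known: {sorted(_TERM_COLUMNS)}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"duplicate terms in candidate {self.label!r}")

    @property
    def column_names(self) -> list[str]:
        cols = ["intercept"]
        for t in self.terms:
            cols.extend(_TERM_COLUMNS[t])
        return cols


EQ1_CANDIDATE = CandidateSpec("seasonal-bmi-sex", EQ1_TERMS)


def default_candidates() -> list[CandidateSpec]:
    """A default comparison set spanning the named determinants.

    Covers one vs two harmonics, the BMI terms, sex main effect and
    sex-by-season interaction, and age terms; it does not claim to
    enumerate any particular historical search.
    """
    return [
        CandidateSpec("harmonics1-only", ("harmonics1",)),
        CandidateSpec("harmonics12", ("harmonics1", "harmonics2")),
        CandidateSpec("harmonics12-bmi", ("harmonics1", "harmonics2", "tbmi", "tbmi_sq")),
        CandidateSpec("harmonics12-bmi-sex",
                      ("harmonics1", "harmonics2", "tbmi", "tbmi_sq", "sex")),
        EQ1_CANDIDATE,
        CandidateSpec("seasonal-bmi-sex+age", EQ1_TERMS + ("age",)),
        CandidateSpec("seasonal-bmi-sex+age-sex", EQ1_TERMS + ("age", "age_sex")),
    ]


@dataclass(frozen=True)
class FitResult:
    """An OLS fit of one candidate on the sqrt scale."""

    params: dict[str, float]
    se: dict[str, float]
    sigma_eps: float
    n: int
    rss: float
    r_squared: float
    bic: float
    term_labels: tuple[str, ...]
    candidate: CandidateSpec

    def to_model(self, provenance: str = "refit") -> ModelCoefficients:
        """Embed the fit into the fixed 10-term layout, absent terms = 0.

        Raises if the candidate contains columns outside that layout
        (e.g. an age effect), which cannot be represented.
        """
        extra = [c for c in self.params if c not in TERM_NAMES]
        if extra:
            raise ValueError(
                f"candidate {self.candidate.label!r} has terms outside the "
                f"10-coefficient layout: {extra}"
            )
        beta = tuple(self.params.get(name, 0.0) for name in TERM_NAMES)
        return ModelCoefficients(beta=beta, sigma_eps=self.sigma_eps,
                                 provenance=provenance)


def build_design(cohort: pd.DataFrame, candidate: CandidateSpec) -> pd.DataFrame:
    """Expand a cohort table into the candidate's design columns."""
    for col in ("sex", "bmi", "day"):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    X10 = design_matrix(cohort["sex"].to_numpy(), cohort["bmi"].to_numpy(),
                        cohort["day"].to_numpy())
    base = pd.DataFrame(X10, columns=list(TERM_NAMES), index=cohort.index)
    base["female"] = (cohort["sex"].to_numpy() == "F").astype(float)
    needed = set(candidate.column_names)
    if needed & {"age", "age_x_female", "age_x_tbmi"}:
        if "age" not in cohort.columns:
            raise ValueError("candidate uses age but cohort has no 'age' column")
        age = cohort["age"].to_numpy(dtype=float)
        base["age"] = age
        base["age_x_female"] = age * base["female"].to_numpy()
        base["age_x_tbmi"] = age * base["tbmi"].to_numpy()
    return base[candidate.column_names]


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    dependent = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if dependent:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {dependent}"
        )


def fit(cohort: pd.DataFrame, candidate: CandidateSpec = EQ1_CANDIDATE) -> FitResult:
    """OLS fit of one candidate on sqrt(25(OH)D).

    Rows with missing 25(OH)D raise; rows with missing covariates used
    by the candidate are dropped listwise with a logged count.
    """
    if "vitd" not in cohort.columns:
        raise ValueError("cohort has no 'vitd' column")
    missing = cohort.index[cohort["vitd"].isna()]
    if len(missing):
        raise ValueError(f"missing 25(OH)D in rows {list(missing[:20])}"
                         + (" ..." if len(missing) > 20 else ""))
    X = build_design(cohort, candidate)
    y = np.sqrt(cohort["vitd"].to_numpy(dtype=float))
    keep = ~X.isna().any(axis=1).to_numpy()
    if not keep.all():
        logger.info("dropping %d rows with missing covariates", (~keep).sum())
        X, y = X.loc[keep], y[keep]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than coefficients ({p})")
    _check_rank(X)
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    rss = float(res.ssr)
    k = p + 1  # + variance parameter
    sigma = math.sqrt(rss / (n - p))
    return FitResult(
        params=dict(zip(X.columns, map(float, res.params))),
        se=dict(zip(X.columns, map(float, res.bse))),
        sigma_eps=sigma,
        n=n,
        rss=rss,
        r_squared=float(res.rsquared),
        bic=_bic(n, rss, k),
        term_labels=tuple(X.columns),
        candidate=candidate,
    )


def _bic(n: int, rss: float, k: int) -> float:
    if rss <= 0:
        raise ValueError("RSS is zero; BIC undefined (perfect interpolation)")
    return n * math.log(rss / n) + k * math.log(n)


def bic(result: FitResult) -> float:
    """n*ln(RSS/n) + k*ln(n), k counting coefficients plus the variance."""
    return _bic(result.n, result.rss, len(result.term_labels) + 1)


def select_model(cohort: pd.DataFrame, candidates=None):
    """Fit every candidate and pick the minimal-BIC one.

    Returns ``(best FitResult, BIC table)``; ties and unfittable
    candidates are resolved deterministically by candidate order.
    """
    if candidates is None:
        candidates = default_candidates()
    if not candidates:
        raise ValueError("need at least one candidate")
    rows, fits = [], []
    for cand in candidates:
        try:
            f = fit(cohort, cand)
        except np.linalg.LinAlgError as exc:
            logger.warning("candidate %s skipped: %s", cand.label, exc)
            rows.append({"candidate": cand.label, "k": None, "rss": None,
                         "bic": None, "selected": False})
            fits.append(None)
            continue
        rows.append({"candidate": cand.label, "k": len(f.term_labels) + 1,
                     "rss": f.rss, "bic": f.bic, "selected": False})
        fits.append(f)
    if all(f is None for f in fits):
        raise np.linalg.LinAlgError("all candidates were rank deficient")
    best_i = min((i for i, f in enumerate(fits) if f is not None),
                 key=lambda i: fits[i].bic)
    rows[best_i]["selected"] = True
    return fits[best_i], pd.DataFrame(rows)
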