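"""Goodness-of-fit by predicted-quantile uniformity.

If the model is correctly specified, the quantile assigned to each
observation — Phi((sqrt(y) - yhat)/sigma_eps) — is uniform on (0, 1).
This module converts a cohort into its predicted quantiles and
summarises departure from uniformity: the one-sample Kolmogorov-Smirnov
statistic with a bootstrap percentile interval, histogram bin counts,
and observed tail proportions below chosen centiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import CalibrationLine, pb_apply
from .model import ModelCoefficients, design_matrix

__all__ = [
    "QuantileDiagnostics",
    "predicted_quantiles",
    "ks_uniform",
    "bootstrap_ks_ci",
    "proportion_below",
    "diagnose",
]

DEFAULT_ALPHAS = (0.03, 0.05, 0.10, 0.25, 0.50)


@dataclass(frozen=True)
class QuantileDiagnostics:
    quantiles: np.ndarray
    ks_stat: float
    ks_ci: tuple[float, float]
    bin_counts: np.ndarray
    prop_below: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.quantiles)


def predicted_quantiles(model: ModelCoefficients, cohort: pd.DataFrame) -> np.ndarray:
    """Per-observation predicted quantiles of measured 25(OH)D."""
    if "vitd" not in cohort.columns:
        raise ValueError("cohort has no 'vitd' column")
    missing = cohort.index[cohort["vitd"].isna()]
    if len(missing):
        raise ValueError(f"missing 25(OH)D in rows {list(missing[:20])}"
                         + (" ..." if len(missing) > 20 else ""))
    v = cohort["vitd"].to_numpy(dtype=float)
    if np.any(v < 0):
        raise ValueError("negative 25(OH)D values")
    X = design_matrix(cohort["sex"].to_numpy(), cohort["bmi"].to_numpy(),
                      cohort["day"].to_numpy())
    yhat = X @ model.beta_array
    return norm.cdf((np.sqrt(v) - yhat) / model.sigma_eps)


def ks_uniform(quantiles) -> float:
    """One-sample KS statistic of values in (0,1) against Uniform(0,1).

    Uses the order-statistic formula
    ``max_i max(i/n - u_(i), u_(i) - (i-1)/n)``.
    """
    u = np.sort(np.asarray(quantiles, dtype=float))
    if u.size == 0:
        raise ValueError("need at least one quantile")
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("quantiles must lie strictly in (0, 1)")
    n = u.size
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))


def bootstrap_ks_ci(quantiles, B: int = 1000, seed: int = 0,
                    conf: float = 0.95) -> tuple[float, float]:
    """Nonparametric bootstrap percentile interval for the KS statistic."""
    u = np.asarray(quantiles, dtype=float)
    if u.size < 2:
        raise ValueError("need at least 2 quantiles to bootstrap")
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    rng = np.random.default_rng(seed)
    n = u.size
    stats = np.empty(B)
    for b in range(B):
        stats[b] = ks_uniform(u[rng.integers(0, n, n)])
    lo, hi = np.quantile(stats, [(1 - conf) / 2, (1 + conf) / 2])
    return float(lo), float(hi)


def proportion_below(quantiles, alphas) -> pd.DataFrame:
    """Observed fraction of predicted quantiles strictly below each alpha.

    Near-nominal fractions (0.10 observed below alpha = 0.10) indicate
    calibrated tails.
    """
    u = np.asarray(quantiles, dtype=float)
    alphas = list(alphas)
    if any(not 0 < a < 1 for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    rows = [{"alpha": a, "observed": float(np.mean(u < a)) if u.size else float("nan")}
            for a in alphas]
    return pd.DataFrame(rows, columns=["alpha", "observed"])


def diagnose(
    model: ModelCoefficients,
    cohort: pd.DataFrame,
    *,
    calibration: CalibrationLine | None = None,
    direction: str = "b_to_a",
    B: int = 1000,
    seed: int = 0,
    bins: int = 20,
    alphas=DEFAULT_ALPHAS,
) -> QuantileDiagnostics:
    """Full uniformity diagnostic, optionally recalibrating the assay first.

    When ``calibration`` is given, measured values are mapped across the
    line before computing quantiles; a sqrt-scale line is applied to
    sqrt-transformed values and the result squared back.
    """
    cohort = cohort.copy()
    if calibration is not None:
        v = cohort["vitd"].to_numpy(dtype=float)
        if calibration.scale == "sqrt":
            cohort["vitd"] = pb_apply(calibration, np.sqrt(v), direction,
                                      scale="sqrt") ** 2
        else:
            cohort["vitd"] = np.clip(
                pb_apply(calibration, v, direction, scale="original"), 0.0, None)
    q = predicted_quantiles(model, cohort)
    # guard exact 0/1 from clamped values for the KS formula
    eps = np.finfo(float).tiny
    q = np.clip(q, eps, 1 - 1e-16)
    ks = ks_uniform(q)
    ci = bootstrap_ks_ci(q, B=B, seed=seed)
    counts, _ = np.histogram(q, bins=bins, range=(0.0, 1.0))
    return QuantileDiagnostics(
        quantiles=q,
        ks_stat=ks,
        ks_ci=ci,
        bin_counts=counts,
        prop_below=proportion_below(q, alphas),
    )


def plot_diagnostics(diag: QuantileDiagnostics, path_hist=None, path_ecdf=None):
    """Histogram and ECDF-vs-diagonal plots; written to file if paths given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figs = []
    if path_hist is not None:
        fig, ax = plt.subplots()
        edges = np.linspace(0, 1, len(diag.bin_counts) + 1)
        ax.bar(edges[:-1], diag.bin_counts, width=np.diff(edges), align="edge",
               edgecolor="white")
        ax.axhline(diag.n / len(diag.bin_counts), color="k", ls="--")
        ax.set_xlabel("predicted quantile")
        ax.set_ylabel("count")
        fig.savefig(path_hist, dpi=120)
        plt.close(fig)
        figs.append(path_hist)
    if path_ecdf is not None:
        fig, ax = plt.subplots()
        u = np.sort(diag.quantiles)
        ax.step(u, np.arange(1, len(u) + 1) / len(u), where="post")
        ax.plot([0, 1], [0, 1], "k--")
        ax.set_xlabel("predicted quantile")
        ax.set_ylabel("ECDF")
        fig.savefig(path_ecdf, dpi=120)
        plt.close(fig)
        figs.append(path_ecdf)
    return figs
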