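"""File formats: model and calibration documents, cohort CSV.

Model and calibration lines are stored as flat JSON key-value documents
with a ``schema_version`` field.  Cohorts travel as CSV with columns
``sex`` (M/F), ``age``, ``bmi``, ``date`` (ISO-8601) or ``day``
(integer 1..365), ``vitd_nmol_l`` and optional ``supplemented`` (0/1,
blank for unknown).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .calibration import CalibrationLine
from .model import ModelCoefficients, day_of_year

MODEL_SCHEMA_VERSION = 1
CALIBRATION_SCHEMA_VERSION = 1

COHORT_COLUMNS = ["sex", "age", "bmi", "day", "vitd_nmol_l", "supplemented"]


def _canonical_json(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def write_model(model: ModelCoefficients, path) -> None:
    """Write coefficients to a flat JSON document (bit-exact round-trip)."""
    doc = {"schema_version": MODEL_SCHEMA_VERSION, "provenance": model.provenance}
    for i, b in enumerate(model.beta):
        doc[f"beta{i}"] = b
    doc["sigma_eps"] = model.sigma_eps
    Path(path).write_text(_canonical_json(doc))


def read_model(path) -> ModelCoefficients:
    doc = json.loads(Path(path).read_text())
    missing = [k for k in [f"beta{i}" for i in range(10)] + ["sigma_eps"] if k not in doc]
    if missing:
        raise ValueError(f"model file {path} missing fields: {missing}")
    if any(f"beta{i}" in doc for i in range(10, 20)):
        raise ValueError(f"model file {path} has more than 10 beta fields")
    return ModelCoefficients(
        beta=tuple(doc[f"beta{i}"] for i in range(10)),
        sigma_eps=doc["sigma_eps"],
        provenance=doc.get("provenance", "unspecified"),
    )


def write_calibration(line: CalibrationLine, path) -> None:
    doc = {
        "schema_version": CALIBRATION_SCHEMA_VERSION,
        "intercept": line.intercept,
        "slope": line.slope,
        "ci_intercept": list(line.ci_intercept),
        "ci_slope": list(line.ci_slope),
        "scale": line.scale,
        "n_pairs": line.n_pairs,
    }
    Path(path).write_text(_canonical_json(doc))


def read_calibration(path) -> CalibrationLine:
    doc = json.loads(Path(path).read_text())
    for k in ("intercept", "slope", "scale"):
        if k not in doc:
            raise ValueError(f"calibration file {path} missing field {k!r}")
    return CalibrationLine(
        intercept=doc["intercept"],
        slope=doc["slope"],
        ci_intercept=tuple(doc.get("ci_intercept", (float("nan"), float("nan")))),
        ci_slope=tuple(doc.get("ci_slope", (float("nan"), float("nan")))),
        scale=doc["scale"],
        n_pairs=int(doc.get("n_pairs", 0)),
    )


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, converting a ``date`` column to day-of-year."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "day" not in df.columns:
        if "date" not in df.columns:
            raise ValueError(f"cohort file {path} needs a 'day' or 'date' column")
        dates = pd.to_datetime(df["date"], format="ISO8601")
        df["day"] = [day_of_year(d.month, d.day) for d in dates]
    df["day"] = df["day"].astype(int)
    if "sex" not in df.columns:
        raise ValueError(f"cohort file {path} needs a 'sex' column")
    df["sex"] = df["sex"].astype(str).str.strip().str.upper().str[0]
    bad = ~df["sex"].isin(["M", "F"])
    if bad.any():
        raise ValueError(f"unrecognised sex codes in rows {list(df.index[bad])}")
    if "vitd_nmol_l" in df.columns and "vitd" not in df.columns:
        df = df.rename(columns={"vitd_nmol_l": "vitd"})
    if "supplemented" in df.columns:
        df["supplemented"] = df["supplemented"].astype("boolean")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "vitd" in out.columns:
        out = out.rename(columns={"vitd": "vitd_nmol_l"})
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


def write_bic_table(table: pd.DataFrame, path) -> None:
    """BIC comparison table: candidate label, k, rss, bic, selected flag."""
    table.to_csv(path, index=False)
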