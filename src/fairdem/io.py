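"""Delimited-text readers/writers for the pipeline's tables.

All tables are comma-separated with ISO-8601 dates; a visit row carries its
diagnosis categories as a semicolon-joined list.  Code-to-category mapping
files are two-column TSV (code, category).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

_PATIENT_DATES = ["birth_date", "first_record_date", "last_record_date",
                  "dementia_onset_date"]


def _write_with_dates(df: pd.DataFrame, path, date_cols: list[str]) -> None:
    out = df.copy()
    for col in date_cols:
        if col in out:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d").fillna("")
    out.to_csv(path, index=False)


def write_patients(patients: pd.DataFrame, path) -> None:
    _write_with_dates(patients, path, _PATIENT_DATES)


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _PATIENT_DATES:
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    return df


def write_visits(visits: pd.DataFrame, path) -> None:
    _write_with_dates(visits, path, ["visit_date"])


def read_visits(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype={"categories": str})
    df["visit_date"] = pd.to_datetime(df["visit_date"], format="%Y-%m-%d")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    _write_with_dates(cohort, path, ["index_date"])


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                     dtype={"exclusion_reason": str})
    df["index_date"] = pd.to_datetime(df["index_date"], format="%Y-%m-%d",
                                      errors="coerce")
    df["eligible"] = df["eligible"].astype(bool)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    df["age_at_index"] = df["age_at_index"].astype("Int64")
    return df


def read_mapping(path) -> dict[str, int]:
    """Two-column TSV: diagnosis-code string -> 1-based category id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, header=0)
    code_col, cat_col = df.columns[:2]
    return dict(zip(df[code_col].astype(str), df[cat_col].astype(int)))


def write_features(X: pd.DataFrame, labels, manifest: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = X.copy()
    out.insert(0, "label", pd.Series(labels, index=X.index))
    out.to_csv(outdir / "features.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_features(outdir) -> tuple[pd.DataFrame, pd.Series, dict]:
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "features.csv", index_col="patient_id")
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    labels = df.pop("label")
    return df[manifest["columns"]], labels, manifest
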