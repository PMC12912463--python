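"""Fixed-length feature vectors from observation-window visits.

Each eligible cohort member is encoded as the concatenation of

* ``observation_years`` annual diagnosis-category count blocks (block 1 is
  the most recent year before the index date; each visit contributes a
  one-hot vector over its *unique* categories, summed within the year),
* sex (0 = male, 1 = female) and age in completed years at the index date,
* one binary no-visit indicator per year (1 = no visits that year,
  regardless of whether any code mapped to a category).

Yearly windows are anniversary-aligned to the index date and half-open:
a visit on the index date itself contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TimelineConfig
from .cohort import shift_years

SEX_CODING = {"M": 0, "F": 1}


def visit_vector(categories, n_categories: int) -> np.ndarray:
    """Indicator vector over 1-based category identifiers (set semantics)."""
    vec = np.zeros(n_categories, dtype=np.int64)
    for c in set(categories):
        c = int(c)
        if not 1 <= c <= n_categories:
            raise ValueError(f"category {c} outside 1..{n_categories}")
        vec[c - 1] = 1
    return vec


def feature_columns(n_categories: int, observation_years: int = 5) -> list[str]:
    cols = [
        f"y{y}_c{c}"
        for y in range(1, observation_years + 1)
        for c in range(1, n_categories + 1)
    ]
    return cols + ["sex", "age_at_index"] + [
        f"novisit_y{y}" for y in range(1, observation_years + 1)
    ]


def build_manifest(n_categories: int, observation_years: int = 5) -> dict:
    cols = feature_columns(n_categories, observation_years)
    nominal = ["sex"] + [f"novisit_y{y}" for y in range(1, observation_years + 1)]
    return {
        "columns": cols,
        "n_categories": n_categories,
        "observation_years": observation_years,
        "nominal_columns": nominal,
        "continuous_columns": [c for c in cols if c not in nominal],
        "sex_coding": SEX_CODING,
    }


def _windowed_visits(
    cohort: pd.DataFrame, visits: pd.DataFrame, observation_years: int
) -> pd.DataFrame:
    """Visits falling in each member's half-open observation window, with a
    1-based ``year`` offset (1 = most recent year before the index date)."""
    members = cohort.loc[cohort["index_date"].notna(),
                         ["patient_id", "index_date"]].copy()
    bounds = {"patient_id": members["patient_id"], "b0": members["index_date"]}
    for y in range(1, observation_years + 1):
        bounds[f"b{y}"] = shift_years(members["index_date"], -y)
    bounds = pd.DataFrame(bounds)
    v = visits.merge(bounds, on="patient_id", how="inner")
    keep = (v["visit_date"] < v["b0"]) & (v["visit_date"] >= v[f"b{observation_years}"])
    v = v.loc[keep].copy()
    year = np.ones(len(v), dtype=np.int64)
    for y in range(1, observation_years):
        year += (v["visit_date"] < v[f"b{y}"]).to_numpy()
    v["year"] = year
    return v.drop(columns=[f"b{y}" for y in range(observation_years + 1)])


def visit_year_offsets(
    cohort: pd.DataFrame, visits: pd.DataFrame, observation_years: int = 5
) -> pd.DataFrame:
    """(patient_id, year) pairs for every in-window visit; used both for the
    no-visit indicators and the missed-years completeness statistic."""
    return _windowed_visits(cohort, visits, observation_years)[["patient_id", "year"]]


@dataclass
class FeatureMatrix:
    """Feature matrix plus its machine-readable column manifest."""

    X: pd.DataFrame
    labels: pd.Series
    manifest: dict
    n_unmapped_codes: int = 0
    log: dict = field(default_factory=dict)


def build_feature_matrix(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    n_categories: int,
    timeline: TimelineConfig | None = None,
    mapping: dict | None = None,
) -> FeatureMatrix:
    """Featurize all eligible cohort members.

    ``mapping`` maps raw diagnosis-code strings to 1-based category
    identifiers; unknown codes are dropped with a logged count.  Without a
    mapping, the visit table's category tokens are taken as identifiers
    directly and must lie in ``1..n_categories``.
    """
    timeline = timeline or TimelineConfig()
    obs = timeline.observation_years
    elig = cohort.loc[cohort["eligible"]].reset_index(drop=True)
    cols = feature_columns(n_categories, obs)
    manifest = build_manifest(n_categories, obs)
    if elig.empty:
        X = pd.DataFrame(columns=cols, dtype=float)
        return FeatureMatrix(X, pd.Series(dtype=int), manifest)

    pos = pd.Series(np.arange(len(elig)), index=elig["patient_id"])
    v = _windowed_visits(elig, visits, obs)
    v = v.reset_index(drop=True)
    v["visit_id"] = np.arange(len(v))

    n = len(elig)
    counts = np.zeros((n, obs * n_categories), dtype=np.int64)
    novisit = np.ones((n, obs), dtype=np.int64)
    n_unmapped = 0
    if len(v):
        vpos = pos[v["patient_id"]].to_numpy()
        seen = np.zeros((n, obs), dtype=bool)
        seen[vpos, v["year"].to_numpy() - 1] = True
        novisit = (~seen).astype(np.int64)

        tokens = v["categories"].fillna("").astype(str).str.split(";")
        pairs = v[["visit_id", "year"]].assign(token=tokens).explode("token")
        pairs = pairs[pairs["token"].astype(str).str.len() > 0]
        if mapping is not None:
            cat = pairs["token"].map(mapping)
            n_unmapped = int(cat.isna().sum())
            pairs = pairs.assign(cat=cat).dropna(subset=["cat"])
            pairs["cat"] = pairs["cat"].astype(int)
        else:
            pairs = pairs.assign(cat=pairs["token"].astype(int))
        if len(pairs):
            if (pairs["cat"] < 1).any() or (pairs["cat"] > n_categories).any():
                bad = pairs.loc[
                    (pairs["cat"] < 1) | (pairs["cat"] > n_categories), "cat"
                ].iloc[0]
                raise ValueError(f"category {bad} outside 1..{n_categories}")
            # one-hot per visit: a category listed twice in one visit counts once
            pairs = pairs.drop_duplicates(["visit_id", "cat"])
            vpos_pairs = vpos[pairs["visit_id"].to_numpy()]
            col = (pairs["year"].to_numpy() - 1) * n_categories + (
                pairs["cat"].to_numpy() - 1
            )
            np.add.at(counts, (vpos_pairs, col), 1)

    sex = elig["sex"].map(SEX_CODING)
    if sex.isna().any():
        raise ValueError("sex must be coded 'M' or 'F'")
    X = pd.DataFrame(counts, columns=cols[: obs * n_categories], dtype=float)
    X["sex"] = sex.astype(float).to_numpy()
    X["age_at_index"] = elig["age_at_index"].astype(float).to_numpy()
    for y in range(1, obs + 1):
        X[f"novisit_y{y}"] = novisit[:, y - 1].astype(float)
    X.index = pd.Index(elig["patient_id"], name="patient_id")
    labels = pd.Series(elig["label"].to_numpy(), index=X.index, name="label")
    return FeatureMatrix(
        X[cols], labels, manifest, n_unmapped, {"n_members": n, "n_visits": int(len(v))}
    )


def annual_blocks(
    member,
    visits: pd.DataFrame,
    n_categories: int,
    timeline: TimelineConfig | None = None,
    mapping: dict | None = None,
) -> np.ndarray:
    """Feature vector for a single eligible cohort member (row-like)."""
    cohort = pd.DataFrame([dict(member)])
    if "eligible" not in cohort:
        cohort["eligible"] = True
    fm = build_feature_matrix(cohort, visits, n_categories, timeline, mapping)
    if fm.X.empty:
        raise ValueError("member is not eligible; no feature vector defined")
    return fm.X.iloc[0].to_numpy()
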