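"""Cohort construction: index dates, SES dichotomization, eligibility filters.

Cases anchor prediction at an index date one prediction-window before their
first recorded dementia onset; controls receive index dates by age
frequency matching against the case age distribution (histogram draw +
rejection against record-span feasibility).  Exclusions are tracked with
exactly one primary reason code per excluded member:

* ``age_lt_min`` — case younger than the minimum age at the incident date;
* ``insufficient_followup`` — control without a feasible index date leaving
  at least one prediction window of follow-up;
* ``no_observation_record`` — no visit inside the observation window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MEASURES, SesDichotomyConfig, TimelineConfig
from .exceptions import MeasureRangeError

EXCLUSION_REASONS = ("age_lt_min", "insufficient_followup", "no_observation_record")

COHORT_COLUMNS = [
    "patient_id",
    "label",
    "index_date",
    "age_at_index",
    "sex",
    "ses_m1",
    "ses_m2",
    "ses_m3",
    "eligible",
    "exclusion_reason",
]


def _is_leap(year):
    return ((year % 4 == 0) & (year % 100 != 0)) | (year % 400 == 0)


def shift_years(dates: pd.Series, years: int) -> pd.Series:
    """Calendar-anniversary shift (Feb 29 clamps to Feb 28); NaT passes through."""
    dates = pd.Series(pd.to_datetime(dates))
    out = pd.Series(pd.NaT, index=dates.index, dtype="datetime64[ns]")
    ok = dates.notna()
    if ok.any():
        sub = dates[ok]
        y = sub.dt.year + years
        m = sub.dt.month
        d = sub.dt.day
        d = d.where(~((m == 2) & (d == 29) & ~_is_leap(y)), 28)
        out.loc[ok] = pd.to_datetime({"year": y, "month": m, "day": d}).to_numpy()
    return out


def age_in_years(birth: pd.Series, at: pd.Series) -> pd.Series:
    """Completed years between two date series."""
    birth = pd.to_datetime(birth)
    at = pd.to_datetime(at)
    before_anniversary = (at.dt.month < birth.dt.month) | (
        (at.dt.month == birth.dt.month) & (at.dt.day < birth.dt.day)
    )
    return at.dt.year - birth.dt.year - before_anniversary.astype(int)


def dichotomize_ses(
    values,
    measure: str,
    cfg: SesDichotomyConfig | None = None,
    reference_values=None,
):
    """Deterministic low/high assignment for an SES measure.

    Returns ``True`` for low SES.  Accepts a scalar (returns ``bool``) or an
    array/Series (returns a boolean array aligned with the input).  For the
    bottom-quartile rule without a fixed reference threshold, the quartile is
    computed on ``reference_values`` when given, else on ``values`` itself.
    """
    cfg = cfg or SesDichotomyConfig()
    if measure not in cfg.rules:
        raise ValueError(f"no dichotomization rule for measure {measure!r}")
    rule = cfg.rules[measure]
    scalar = np.isscalar(values)
    arr = np.asarray([values] if scalar else values, dtype=float)
    lo, hi = rule.value_range
    finite = ~np.isnan(arr)
    bad = finite & ((arr < lo) | (arr > hi))
    if bad.any():
        raise MeasureRangeError(measure, float(arr[bad][0]))
    if rule.kind in ("upper-range", "decile-range"):
        low = arr >= rule.low_min
    else:  # bottom-quartile
        if rule.reference_threshold is not None:
            cut = rule.reference_threshold
        else:
            ref = arr if reference_values is None else np.asarray(reference_values, dtype=float)
            cut = np.nanquantile(ref, rule.quantile)
        low = arr < cut
    if scalar:
        return bool(low[0])
    if isinstance(values, pd.Series):
        return pd.Series(low, index=values.index)
    return low


def ses_level(is_low) -> np.ndarray:
    """Map boolean low-SES indicators to 'low'/'high' labels."""
    return np.where(np.asarray(is_low), "low", "high")


def _visit_date_lookup(visits: pd.DataFrame) -> dict[str, np.ndarray]:
    if len(visits) == 0:
        return {}
    v = visits[["patient_id", "visit_date"]].sort_values(
        ["patient_id", "visit_date"], kind="stable"
    )
    days = v["visit_date"].to_numpy().astype("datetime64[D]").astype(np.int64)
    return {
        pid: days[idx] for pid, idx in v.groupby("patient_id", sort=False).indices.items()
    }


def _has_visit_in_window(
    lookup: dict[str, np.ndarray], pid: str, lo_day: int, hi_day: int
) -> bool:
    """Any visit with lo_day <= day < hi_day?"""
    days = lookup.get(pid)
    if days is None or len(days) == 0:
        return False
    i = np.searchsorted(days, lo_day, side="left")
    return i < len(days) and days[i] < hi_day


def _days(dates: pd.Series) -> np.ndarray:
    return pd.to_datetime(dates).to_numpy().astype("datetime64[D]").astype(np.int64)


def assign_case_index(patient, cfg: TimelineConfig, visit_dates=None) -> dict:
    """Index-date assignment for a single case (onset minus the prediction
    window); flags ineligibility by age or by an empty observation window
    when ``visit_dates`` (sorted day numbers or datetimes) are supplied."""
    onset = patient["dementia_onset_date"]
    if pd.isna(onset):
        raise ValueError("assign_case_index requires a dementia onset date")
    onset = pd.Timestamp(onset)
    index_date = shift_years(pd.Series([onset]), -cfg.prediction_years).iloc[0]
    birth = pd.Timestamp(patient["birth_date"])
    age_at_incident = int(age_in_years(pd.Series([birth]), pd.Series([onset])).iloc[0])
    age_at_index = int(age_in_years(pd.Series([birth]), pd.Series([index_date])).iloc[0])
    reason = ""
    if age_at_incident < cfg.min_age_at_incident:
        reason = "age_lt_min"
    elif visit_dates is not None:
        days = np.sort(pd.to_datetime(pd.Series(visit_dates)).to_numpy()
                       .astype("datetime64[D]").astype(np.int64))
        lo = int(
            shift_years(pd.Series([index_date]), -cfg.observation_years).iloc[0].to_datetime64()
            .astype("datetime64[D]").astype(np.int64)
        )
        hi = int(index_date.to_datetime64().astype("datetime64[D]").astype(np.int64))
        i = np.searchsorted(days, lo, side="left")
        if not (i < len(days) and days[i] < hi):
            reason = "no_observation_record"
    return {
        "patient_id": patient["patient_id"],
        "label": 1,
        "index_date": index_date,
        "age_at_index": age_at_index,
        "eligible": reason == "",
        "exclusion_reason": reason,
    }


def sample_control_index(
    controls: pd.DataFrame,
    case_ages,
    cfg: TimelineConfig,
    seed: int,
    max_attempts: int = 50,
) -> pd.DataFrame:
    """Frequency-match control index dates to the case age distribution.

    Each control draws a target age from the empirical case-age histogram
    (bins of ``age_bin_width`` anchored at ``age_bin_anchor``), inverts it to
    an index date, and rejection-samples against record-span feasibility:
    the full observation window and at least one prediction window of
    follow-up must lie inside the record span.  Controls with no feasible
    draw after ``max_attempts`` rounds are flagged ``insufficient_followup``.
    """
    case_ages = np.asarray(case_ages, dtype=float)
    if len(case_ages) == 0:
        raise ValueError("case_ages must be non-empty for frequency matching")
    if len(controls) == 0:
        return pd.DataFrame(
            columns=["patient_id", "label", "index_date", "age_at_index", "eligible",
                     "exclusion_reason"]
        )
    rng = np.random.default_rng(seed)
    anchor, width = cfg.age_bin_anchor, cfg.age_bin_width
    bin_idx = ((case_ages - anchor) // width).astype(int)
    uniq, counts = np.unique(bin_idx, return_counts=True)
    probs = counts / counts.sum()

    n = len(controls)
    birth_days = _days(controls["birth_date"])
    first_days = _days(controls["first_record_date"])
    last_days = _days(controls["last_record_date"])
    followup_days = int(np.ceil(365.25 * cfg.prediction_years))
    observation_days = int(np.ceil(365.25 * cfg.observation_years))

    accepted = np.zeros(n, dtype=bool)
    index_days = np.zeros(n, dtype=np.int64)
    for _ in range(max_attempts):
        todo = ~accepted
        if not todo.any():
            break
        k = int(todo.sum())
        bins = rng.choice(uniq, size=k, p=probs)
        ages = anchor + bins * width + rng.random(k) * width
        cand = birth_days[todo] + np.round(ages * 365.25).astype(np.int64)
        ok = (cand - observation_days >= first_days[todo]) & (
            cand + followup_days <= last_days[todo]
        )
        idx = np.nonzero(todo)[0]
        accepted[idx[ok]] = True
        index_days[idx[ok]] = cand[ok]

    index_date = pd.Series(index_days.astype("datetime64[D]").astype("datetime64[ns]"))
    index_date[~accepted] = pd.NaT
    age_at_index = age_in_years(
        controls["birth_date"].reset_index(drop=True), index_date
    )
    out = pd.DataFrame(
        {
            "patient_id": controls["patient_id"].to_numpy(),
            "label": 0,
            "index_date": index_date,
            "age_at_index": age_at_index.astype("float"),
            "eligible": accepted,
            "exclusion_reason": np.where(accepted, "", "insufficient_followup"),
        }
    )
    return out


def build_cohort(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    timeline: TimelineConfig | None = None,
    dichotomy: SesDichotomyConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Compose index assignment, matching, SES dichotomization and filters.

    Returns the cohort table and an exclusion ledger (count per reason code;
    counts sum to input size minus eligible size).
    """
    timeline = timeline or TimelineConfig()
    dichotomy = dichotomy or SesDichotomyConfig()
    lookup = _visit_date_lookup(visits)

    is_case = patients["dementia_onset_date"].notna().to_numpy()
    cases = patients.loc[is_case].reset_index(drop=True)
    controls = patients.loc[~is_case].reset_index(drop=True)

    # Cases: index = onset - prediction window; age filter at the incident.
    case_members = pd.DataFrame(columns=["patient_id", "label", "index_date",
                                         "age_at_index", "eligible", "exclusion_reason"])
    if len(cases):
        onset = pd.to_datetime(cases["dementia_onset_date"])
        index_date = shift_years(onset, -timeline.prediction_years)
        age_at_incident = age_in_years(cases["birth_date"], onset)
        age_at_index = age_in_years(cases["birth_date"], index_date)
        reason = np.where(
            age_at_incident < timeline.min_age_at_incident, "age_lt_min", ""
        ).astype(object)
        case_members = pd.DataFrame(
            {
                "patient_id": cases["patient_id"].to_numpy(),
                "label": 1,
                "index_date": index_date,
                "age_at_index": age_at_index.astype(float),
                "eligible": reason == "",
                "exclusion_reason": reason,
            }
        )

    # Controls: frequency matching against eligible case ages.
    if len(controls) and len(case_members) and case_members["eligible"].any():
        eligible_case_ages = case_members.loc[case_members["eligible"], "age_at_index"]
        control_members = sample_control_index(
            controls, eligible_case_ages.to_numpy(), timeline, seed
        )
    else:
        control_members = sample_control_index(
            controls, case_members["age_at_index"].to_numpy(), timeline, seed
        ) if len(controls) else pd.DataFrame(
            columns=["patient_id", "label", "index_date", "age_at_index",
                     "eligible", "exclusion_reason"]
        )

    members = pd.concat([case_members, control_members], ignore_index=True)

    # Observation-window record requirement (primary reason only for members
    # not already excluded).
    obs_lo = shift_years(members["index_date"], -timeline.observation_years)
    lo_days = obs_lo.to_numpy().astype("datetime64[D]").astype("float")
    hi_days = members["index_date"].to_numpy().astype("datetime64[D]").astype("float")
    has_obs = np.zeros(len(members), dtype=bool)
    for i, pid in enumerate(members["patient_id"].to_numpy()):
        if np.isnan(lo_days[i]):
            continue
        has_obs[i] = _has_visit_in_window(lookup, pid, int(lo_days[i]), int(hi_days[i]))
    newly_excluded = members["eligible"].to_numpy() & ~has_obs
    members.loc[newly_excluded, "eligible"] = False
    members.loc[newly_excluded, "exclusion_reason"] = "no_observation_record"

    # Optional control:case downsampling among eligible controls.
    ledger = {r: int((members["exclusion_reason"] == r).sum()) for r in EXCLUSION_REASONS}
    if timeline.control_case_ratio != "all":
        ratio = float(timeline.control_case_ratio)
        n_cases = int(((members["label"] == 1) & members["eligible"]).sum())
        elig_ctrl = members.index[(members["label"] == 0) & members["eligible"]]
        target = int(round(ratio * n_cases))
        if len(elig_ctrl) > target:
            rng = np.random.default_rng(seed + 1)
            drop = rng.choice(elig_ctrl, size=len(elig_ctrl) - target, replace=False)
            members = members.drop(index=drop).reset_index(drop=True)
            ledger["not_sampled"] = int(len(drop))

    # SES dichotomization; empirical quantile rules use the eligible cohort.
    merged = members.merge(
        patients[["patient_id", "sex", "ses_m1", "ses_m2", "ses_m3"]],
        on="patient_id",
        how="left",
    )
    eligible_mask = merged["eligible"].to_numpy()
    for m in MEASURES:
        raw = merged[f"ses_{m}"]
        low = dichotomize_ses(raw, m, dichotomy, reference_values=raw[eligible_mask])
        merged[f"ses_{m}"] = ses_level(low)
    cohort = merged[COHORT_COLUMNS].copy()
    cohort["age_at_index"] = cohort["age_at_index"].astype("Int64")
    return cohort, ledger
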