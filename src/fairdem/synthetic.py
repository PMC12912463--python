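"""Seeded synthetic EHR cohort generator.

Emulates the statistical structure the downstream audit assumes, without any
real patient data:

* three partially concordant SES measures derived from correlated latent
  normal deprivation factors, thresholded at measure-specific quantiles;
* an SES-graded visit process — a per-year Bernoulli "any visit" gate
  (empty-year probability higher for low-SES patients) followed by a
  truncated-Poisson visit count whose mean depends on case status;
* per-visit diagnosis-category recording with case/control prevalence
  differences, degraded for low-SES patients by a recording-dropout
  probability (``ses_signal_strength``).

Low SES degrades only data completeness (missingness and recording dropout),
never the true outcome process: the generator encodes the
data-completeness explanation for subgroup performance gaps.

Dates live on a 2004-2020 simulated calendar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import MEASURES, PopulationConfig, SesDichotomyConfig, TimelineConfig
from .exceptions import InfeasibleConcordanceError, UndefinedMetricError

CALENDAR_START = np.datetime64("2004-01-01")
CALENDAR_END = np.datetime64("2020-12-31")

#: Age-at-anchor distribution (years): (low, high, probability) per bin.
AGE_BINS = (
    (50, 55, 0.015),
    (55, 65, 0.065),
    (65, 75, 0.185),
    (75, 85, 0.425),
    (85, 95, 0.285),
    (95, 100, 0.025),
)

_PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "first_record_date",
    "last_record_date",
    "dementia_onset_date",
    "ses_m1",
    "ses_m2",
    "ses_m3",
]
_VISIT_COLUMNS = ["patient_id", "visit_date", "categories"]

# Measure-scale anchors tying raw SES values to the default dichotomy rules:
# m1 low iff value < 25 (0-100 reference-percentile housing scale),
# m2 low iff value >= 76 (0-100 deprivation percentile),
# m3 low iff decile >= 8 (1-10 state decile scale).
_M1_CUT_Q = 0.25
_M2_CUT_Q = 0.76
_M3_CUT_Q = 0.70


def _bvn_upper_orthant(q_i: float, q_j: float, rho: float) -> float:
    """P(X > q_i, Y > q_j) for standard bivariate normal with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([-q_i, -q_j]))


def solve_pairwise_correlation(p_i: float, p_j: float, joint: float) -> float:
    """Latent-normal correlation reproducing P(low_i and low_j) = joint.

    Raises :class:`InfeasibleConcordanceError` outside the Frechet bounds
    max(0, p_i + p_j - 1) <= joint <= min(p_i, p_j).
    """
    lo_bound = max(0.0, p_i + p_j - 1.0)
    hi_bound = min(p_i, p_j)
    if not lo_bound <= joint <= hi_bound:
        raise InfeasibleConcordanceError(
            f"joint low-SES probability {joint:.4f} outside Frechet bounds "
            f"[{lo_bound:.4f}, {hi_bound:.4f}] for marginals {p_i:.4f}, {p_j:.4f}"
        )
    q_i = stats.norm.ppf(1.0 - p_i)
    q_j = stats.norm.ppf(1.0 - p_j)

    def objective(rho: float) -> float:
        return _bvn_upper_orthant(q_i, q_j, rho) - joint

    lo, hi = -0.999, 0.999
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise InfeasibleConcordanceError(
            f"no latent correlation in (-0.999, 0.999) achieves joint {joint:.4f} "
            f"for marginals {p_i:.4f}, {p_j:.4f}"
        )
    return float(optimize.brentq(objective, lo, hi, xtol=1e-10))


def latent_correlation_matrix(cfg: PopulationConfig) -> np.ndarray:
    """3x3 latent correlation matrix realizing the configured concordances."""
    p = np.asarray(cfg.low_ses_fraction)
    R = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            joint = cfg.concordance_targets[i, j] * p[i]
            R[i, j] = R[j, i] = solve_pairwise_correlation(p[i], p[j], joint)
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-8:
        raise InfeasibleConcordanceError(
            "pairwise concordance targets are jointly infeasible: implied "
            f"latent correlation matrix is not PSD (min eigenvalue {eigvals.min():.3g})"
        )
    return R


def _solve_visit_category_prob(
    target: float,
    lam: float,
    empty_probs: tuple[float, float],
    low_weight: float,
    dropout: float,
    years: int = 5,
) -> float:
    """Per-visit recording probability such that the *population-level*
    window prevalence (mixing high and low SES, with dropout and empty-year
    gates) matches ``target``.

    Uses the closed form E[(1-p)^K] = (1-p) exp(-(lam-1) p) for the shifted
    Poisson visit count K = 1 + Poisson(lam-1).
    """
    if target <= 0.0:
        return 0.0
    e_high, e_low = empty_probs
    lam_excess = max(lam - 1.0, 0.0)

    def window_prev(pi: float) -> float:
        total = 0.0
        for w, e, drop in ((1.0 - low_weight, e_high, 0.0), (low_weight, e_low, dropout)):
            pe = pi * (1.0 - drop)
            yearly_no_record = e + (1.0 - e) * (1.0 - pe) * np.exp(-lam_excess * pe)
            total += w * (1.0 - yearly_no_record**years)
        return total

    hi = 1.0 - 1e-9
    if window_prev(hi) < target:
        raise ValueError(
            f"category window prevalence {target:.3f} unreachable at "
            f"visit rate {lam:.2f}"
        )
    return float(optimize.brentq(lambda x: window_prev(x) - target, 1e-12, hi, xtol=1e-12))


def _calibrate_empty_gate(target: float, lam: float) -> float:
    """Calendar-year gate probability whose *observed* anniversary-aligned
    empty-window-year rate equals ``target``.

    Feature windows are anniversary-aligned to the index date, so one window
    year overlaps two gated calendar years with phase fractions (phi, 1-phi);
    an open calendar year of K = 1 + Poisson(lam-1) uniform visits still
    leaves a fragment of length f empty with probability
    E[(1-f)^K] = (1-f) exp(-(lam-1) f).  The gate is solved so the
    phase-averaged empty probability matches the configured target; when
    sparse visit rates alone already exceed the target the gate clamps to 0.
    """
    if target <= 0.0:
        return 0.0
    lam_excess = max(lam - 1.0, 0.0)
    phis = np.linspace(0.0, 1.0, 201)

    def g(f: np.ndarray) -> np.ndarray:
        return (1.0 - f) * np.exp(-lam_excess * f)

    def observed(e: float) -> float:
        a = e + (1.0 - e) * g(phis)
        b = e + (1.0 - e) * g(1.0 - phis)
        return float(np.trapezoid(a * b, phis))

    if observed(0.0) >= target:
        return 0.0
    if observed(1.0 - 1e-9) <= target:
        return 1.0
    return float(optimize.brentq(lambda e: observed(e) - target, 0.0, 1.0 - 1e-9))


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    lows = np.array([b[0] for b in AGE_BINS], dtype=float)
    highs = np.array([b[1] for b in AGE_BINS], dtype=float)
    probs = np.array([b[2] for b in AGE_BINS])
    idx = rng.choice(len(AGE_BINS), size=n, p=probs / probs.sum())
    return lows[idx] + rng.random(n) * (highs[idx] - lows[idx])


def _empty_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    patients = pd.DataFrame(columns=_PATIENT_COLUMNS)
    for col in ("birth_date", "first_record_date", "last_record_date", "dementia_onset_date"):
        patients[col] = pd.to_datetime(patients[col])
    visits = pd.DataFrame(columns=_VISIT_COLUMNS)
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    return patients, visits


def generate_population(cfg: PopulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate seeded patient and visit tables.

    Returns
    -------
    patients : DataFrame
        One row per person: identifier, sex, birth/record/onset dates and the
        three raw SES measure values.
    visits : DataFrame
        One row per visit: identifier, date and semicolon-joined 1-based
        diagnosis-category identifiers (possibly empty).
    """
    cfg.validate()
    if cfg.n_patients == 0:
        return _empty_tables()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    C = cfg.n_categories
    p1, p2, p3 = cfg.low_ses_fraction

    is_case = rng.random(n) < cfg.case_fraction
    is_female = rng.random(n) < cfg.sex_female_fraction

    # Latent deprivation factors -> raw measure values on their native scales.
    R = latent_correlation_matrix(cfg)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(3))
    d = rng.standard_normal((n, 3)) @ L.T
    s1 = stats.norm.ppf(1.0 - p1) - stats.norm.ppf(1.0 - _M1_CUT_Q)
    c2 = stats.norm.ppf(1.0 - p2) - stats.norm.ppf(_M2_CUT_Q)
    c3 = stats.norm.ppf(1.0 - p3) - stats.norm.ppf(_M3_CUT_Q)
    ses_m1 = 100.0 * stats.norm.cdf(-(d[:, 0] - s1))
    ses_m2 = 100.0 * stats.norm.cdf(d[:, 1] - c2)
    ses_m3 = np.clip(np.floor(10.0 * stats.norm.cdf(d[:, 2] - c3)).astype(int) + 1, 1, 10)
    # Data-completeness degradation is driven by the primary (individual-level)
    # measure's latent factor; identical condition to "m1 value < quartile cut".
    is_low_ses = d[:, 0] > stats.norm.ppf(1.0 - p1)

    # Record spans and key dates (integer days since epoch for vector math).
    start = CALENDAR_START.astype("datetime64[D]").astype(np.int64)
    end = CALENDAR_END.astype("datetime64[D]").astype(np.int64)
    first_rec = start + rng.integers(0, 365, n)
    last_rec = end - rng.integers(0, 365, n)
    ages = _draw_ages(rng, n)
    onset = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    onset_lo = first_rec + int(6 * 365.25)  # leave room for observation history
    span = last_rec - onset_lo
    onset_draw = onset_lo + np.floor(rng.random(n) * (span + 1)).astype(np.int64)
    onset[is_case] = onset_draw[is_case]
    anchor = np.where(
        is_case,
        onset_draw,
        np.datetime64("2011-01-01").astype("datetime64[D]").astype(np.int64)
        + np.floor(rng.random(n) * (8.5 * 365.25)).astype(np.int64),
    )
    birth = anchor - np.round(ages * 365.25).astype(np.int64)

    visits = _generate_visits(cfg, rng, is_case, is_low_ses, first_rec, last_rec)

    patient_id = np.array([f"P{i:06d}" for i in range(n)])

    def _dates(days: np.ndarray) -> pd.Series:
        return pd.Series(days.astype("datetime64[D]").astype("datetime64[ns]"))

    onset_dates = _dates(onset)
    onset_dates[~is_case] = pd.NaT
    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": np.where(is_female, "F", "M"),
            "birth_date": _dates(birth),
            "first_record_date": _dates(first_rec),
            "last_record_date": _dates(last_rec),
            "dementia_onset_date": onset_dates,
            "ses_m1": ses_m1,
            "ses_m2": ses_m2,
            "ses_m3": ses_m3.astype(float),
        }
    )
    visits["patient_id"] = patient_id[visits.pop("patient_idx").to_numpy()]
    visits = visits[_VISIT_COLUMNS].sort_values(
        ["patient_id", "visit_date", "categories"], kind="stable", ignore_index=True
    )
    return patients, visits


def _generate_visits(
    cfg: PopulationConfig,
    rng: np.random.Generator,
    is_case: np.ndarray,
    is_low_ses: np.ndarray,
    first_rec: np.ndarray,
    last_rec: np.ndarray,
) -> pd.DataFrame:
    """Vectorized visit process over the patient x calendar-year grid."""
    n = len(is_case)
    C = cfg.n_categories
    years = np.arange(2004, 2021)
    year_start = np.array([np.datetime64(f"{y}-01-01", "D") for y in years]).astype(np.int64)
    year_end = np.array(
        [np.datetime64(f"{y + 1}-01-01", "D") for y in years]
    ).astype(np.int64)

    lo = np.maximum(first_rec[:, None], year_start[None, :])
    hi = np.minimum(last_rec[:, None] + 1, year_end[None, :])
    in_span = lo < hi

    gates = _empty_gates(cfg)
    empty_p = np.where(
        is_low_ses,
        np.where(is_case, gates[("low", "case")], gates[("low", "control")]),
        np.where(is_case, gates[("high", "case")], gates[("high", "control")]),
    )
    gate = rng.random((n, len(years))) >= empty_p[:, None]
    lam = np.where(
        is_case, cfg.visits_per_year_mean["case"], cfg.visits_per_year_mean["control"]
    )
    counts = 1 + rng.poisson(np.maximum(lam - 1.0, 0.0)[:, None], size=(n, len(years)))
    active = in_span & gate
    counts = np.where(active, counts, 0)

    pidx_grid, _ = np.meshgrid(np.arange(n), np.arange(len(years)), indexing="ij")
    flat_counts = counts[active]
    rep_patient = np.repeat(pidx_grid[active], flat_counts)
    rep_lo = np.repeat(lo[active], flat_counts)
    rep_span = np.repeat((hi - lo)[active], flat_counts)
    m = rep_patient.size
    dates = rep_lo + np.floor(rng.random(m) * rep_span).astype(np.int64)

    # Per-visit category recording, thinned by SES dropout.
    pi = _calibrated_category_probs(cfg)
    case_v = is_case[rep_patient].astype(int)
    keep_factor = np.where(is_low_ses[rep_patient], 1.0 - min(cfg.ses_signal_strength, 1.0), 1.0)
    vid_chunks: list[np.ndarray] = []
    cat_chunks: list[np.ndarray] = []
    for c in range(C):
        p_v = pi[case_v, c] * keep_factor
        hit = rng.random(m) < p_v
        vid_chunks.append(np.nonzero(hit)[0])
        cat_chunks.append(np.full(int(hit.sum()), c + 1, dtype=np.int64))
    if m:
        pairs = pd.DataFrame(
            {
                "vid": np.concatenate(vid_chunks) if vid_chunks else np.array([], dtype=np.int64),
                "cat": np.concatenate(cat_chunks) if cat_chunks else np.array([], dtype=np.int64),
            }
        ).sort_values(["vid", "cat"], kind="stable")
        joined = pairs.groupby("vid")["cat"].agg(lambda s: ";".join(map(str, s)))
        categories = np.full(m, "", dtype=object)
        categories[joined.index.to_numpy()] = joined.to_numpy()
    else:
        categories = np.array([], dtype=object)

    return pd.DataFrame(
        {
            "patient_idx": rep_patient,
            "visit_date": pd.Series(dates.astype("datetime64[D]").astype("datetime64[ns]")),
            "categories": categories,
        }
    )


def _empty_gates(cfg: PopulationConfig) -> dict[tuple[str, str], float]:
    return {
        (ses, status): _calibrate_empty_gate(
            cfg.empty_year_prob[ses], cfg.visits_per_year_mean[status]
        )
        for ses in ("low", "high")
        for status in ("case", "control")
    }


def _calibrated_category_probs(cfg: PopulationConfig) -> np.ndarray:
    """(status, category) per-visit recording probabilities; row 0 = control."""
    p_low = cfg.low_ses_fraction[0]
    gates = _empty_gates(cfg)
    pi = np.zeros((2, cfg.n_categories))
    for row, status in enumerate(("control", "case")):
        lam = cfg.visits_per_year_mean[status]
        empties = (gates[("high", status)], gates[("low", status)])
        for c in range(cfg.n_categories):
            pi[row, c] = _solve_visit_category_prob(
                float(cfg.category_prevalence[status][c]),
                lam,
                empties,
                p_low,
                min(cfg.ses_signal_strength, 1.0),
            )
    return pi


def compute_concordance(
    patients: pd.DataFrame,
    measure_i: str,
    measure_j: str,
    dichotomy: SesDichotomyConfig | None = None,
) -> float:
    """Fraction of patients low-SES on ``measure_i`` that are also low on
    ``measure_j`` under the given dichotomization rules."""
    from .cohort import dichotomize_ses

    dichotomy = dichotomy or SesDichotomyConfig()
    for m in (measure_i, measure_j):
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    low_i = dichotomize_ses(patients[f"ses_{measure_i}"], measure_i, dichotomy)
    low_j = dichotomize_ses(patients[f"ses_{measure_j}"], measure_j, dichotomy)
    n_low_i = int(low_i.sum())
    if n_low_i == 0:
        raise UndefinedMetricError(
            f"no patients are low SES on {measure_i}; concordance undefined"
        )
    return float((low_i & low_j).sum() / n_low_i)


def missed_years_summary(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    timeline: TimelineConfig | None = None,
    measure: str = "m1",
) -> pd.Series:
    """Mean number of empty 1-year windows inside the observation window,
    by SES level of ``measure``.

    Every cohort row must carry an assigned index date.
    """
    from .features import visit_year_offsets

    timeline = timeline or TimelineConfig()
    if cohort["index_date"].isna().any():
        raise ValueError("every cohort member needs an assigned index date")
    offsets = visit_year_offsets(cohort, visits, timeline.observation_years)
    seen = offsets.groupby("patient_id")["year"].nunique()
    covered = cohort["patient_id"].map(seen).fillna(0)
    missed = timeline.observation_years - covered
    return missed.groupby(cohort[f"ses_{measure}"].to_numpy()).mean()
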