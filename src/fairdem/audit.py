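"""Subgroup error metrics, bootstrap uncertainty, significance and
relative-difference summaries.

The audit metric is the balanced error rate

    BER = (FPR + FNR) / 2,

the unweighted mean of the false-positive rate FP/(TN+FP) and the
false-negative rate FN/(TP+FN).  Per SES-by-sex stratum the audit reports
the point BER with a percentile bootstrap CI (within-subgroup resampling,
equal size, B replicates).  Pairwise subgroup comparisons use a two-sample
two-tailed t test on the bootstrap replicate vectors — Welch's form when a
Levene test rejects variance homogeneity at 0.05 — with Benjamini-Hochberg
false-discovery-rate control over all p-values pooled per model.  Because
bootstrap replicates are not independent observations, nominal significance
is inflated; the construction is reported as-is and flags mirror it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import UndefinedMetricError

BASELINE_KEY = ("M", "high")  # "male in high SES" reference subgroup


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exhaustive 2x2 counts for binary label vectors."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for arr in (t, p):
        if len(arr) and not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def false_positive_rate(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no negative instances; FPR undefined")
    return c.fp / (c.tn + c.fp)


def false_negative_rate(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive instances; FNR undefined")
    return c.fn / (c.tp + c.fn)


def balanced_error_rate(c: ConfusionCounts) -> float:
    """(FPR + FNR) / 2; undefined when a class is absent."""
    return (false_positive_rate(c) + false_negative_rate(c)) / 2.0


@dataclass
class BootstrapResult:
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    n_redraws: int = 0


def bootstrap_ber(
    y_true,
    y_pred,
    B: int = 1000,
    seed: int | None = None,
    max_retries: int = 100,
) -> BootstrapResult:
    """B within-subgroup bootstrap replicates of the BER with a percentile
    95% CI.  Replicates whose resample misses a class are redrawn (bounded
    retries, count logged on the result)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    n = len(t)
    c = confusion(t, p)
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("point sample misses an outcome class")
    rng = np.random.default_rng(seed)

    def replicate_bers(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ts, ps = t[idx], p[idx]
        pos = (ts == 1).sum(axis=1)
        neg = idx.shape[1] - pos
        fn = ((ts == 1) & (ps == 0)).sum(axis=1)
        fp = ((ts == 0) & (ps == 1)).sum(axis=1)
        valid = (pos > 0) & (neg > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ber = (fp / neg + fn / pos) / 2.0
        return ber, valid

    idx = rng.integers(0, n, size=(B, n))
    bers, valid = replicate_bers(idx)
    n_redraws = 0
    retries = 0
    while not valid.all() and retries < max_retries:
        bad = ~valid
        n_redraws += int(bad.sum())
        idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
        new_bers, new_valid = replicate_bers(idx_new)
        bers[bad] = new_bers
        valid = valid.copy()
        valid[bad] = new_valid
        retries += 1
    if not valid.all():
        raise UndefinedMetricError(
            "subgroup too small to resample both classes within retry budget"
        )
    lo, hi = np.percentile(bers, [2.5, 97.5])
    return BootstrapResult(bers, float(lo), float(hi), n_redraws)


def compare_groups(
    replicates_a, replicates_b, levene_alpha: float = 0.05
) -> float:
    """Raw two-tailed p for a difference in mean BER between two replicate
    vectors; Levene's test (center=mean) gates Welch vs the standard t."""
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p_lev = stats.levene(a, b, center="mean").pvalue
    equal_var = bool(p_lev >= levene_alpha)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def bh_adjust(p_values, fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance decisions."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject


def relative_ber_difference(ber_low: float, ber_high: float) -> float:
    """(BER_low - BER_high) / BER_high; 0 means parity, negative an inverted
    disparity."""
    if ber_high == 0:
        raise UndefinedMetricError("high-SES BER is zero; relative difference undefined")
    return (ber_low - ber_high) / ber_high


def excess_misclassification(ber_a: float, ber_b: float, n_per_group: int = 1000) -> int:
    """Extra misclassified patients per ``n_per_group`` screened in each
    group when the BER rises from ``ber_a`` to ``ber_b``."""
    if n_per_group < 0:
        raise ValueError("n_per_group must be nonnegative")
    for x in (ber_a, ber_b):
        if not 0.0 <= x <= 1.0:
            raise ValueError("BER values must lie in [0, 1]")
    return int(round((ber_b - ber_a) * n_per_group))


@dataclass
class SubgroupMetrics:
    """Error profile of one SES-by-sex stratum (sex may be 'all' = pooled)."""

    sex: str
    ses: str
    counts: ConfusionCounts
    fpr: float | None
    fnr: float | None
    ber: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    replicates: np.ndarray | None = field(default=None, repr=False)
    note: str = ""


def _strata(pred: pd.DataFrame, measure: str):
    level = pred[f"ses_{measure}"]
    for sex in ("M", "F", "all"):
        sex_mask = np.ones(len(pred), dtype=bool) if sex == "all" else (
            pred["sex"] == sex
        ).to_numpy()
        for ses in ("high", "low"):
            yield sex, ses, sex_mask & (level == ses).to_numpy()


def subgroup_metrics(
    pred: pd.DataFrame,
    measure: str,
    B: int = 1000,
    seed: int | None = None,
) -> list[SubgroupMetrics]:
    """Metrics for the six strata (male/female/pooled x high/low SES).

    ``pred`` needs columns y_true, y_pred, sex and ses_<measure>.  Pooled-sex
    metrics are computed from pooled confusion counts, not by averaging the
    per-sex values.  Degenerate strata (a missing outcome class) are reported
    with their counts and an explanatory note, never dropped.
    """
    out: list[SubgroupMetrics] = []
    for k, (sex, ses, mask) in enumerate(_strata(pred, measure)):
        t = pred.loc[mask, "y_true"].to_numpy()
        p = pred.loc[mask, "y_pred"].to_numpy()
        c = confusion(t, p)
        try:
            fpr, fnr = false_positive_rate(c), false_negative_rate(c)
            ber = (fpr + fnr) / 2.0
            boot = bootstrap_ber(
                t, p, B=B, seed=None if seed is None else seed + k
            )
            out.append(
                SubgroupMetrics(
                    sex, ses, c, fpr, fnr, ber, boot.ci_low, boot.ci_high,
                    boot.replicates,
                )
            )
        except UndefinedMetricError as err:
            out.append(
                SubgroupMetrics(sex, ses, c, None, None, None, note=str(err))
            )
    return out


def metrics_table(groups: list[SubgroupMetrics]) -> pd.DataFrame:
    rows = []
    for g in groups:
        rows.append(
            {
                "sex": g.sex,
                "ses": g.ses,
                "tp": g.counts.tp,
                "fp": g.counts.fp,
                "tn": g.counts.tn,
                "fn": g.counts.fn,
                "fpr": g.fpr,
                "fnr": g.fnr,
                "ber": g.ber,
                "ci_low": g.ci_low,
                "ci_high": g.ci_high,
                "note": g.note,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    key_a: tuple[str, str]
    key_b: tuple[str, str]
    raw_p: float
    significant: bool = False
    direction: str = "none"  # 'higher'/'lower' of key_a vs key_b, gated on BH
    measure: str = ""


def pairwise_contrasts(groups: list[SubgroupMetrics]) -> list[ContrastResult]:
    """Low-vs-high contrasts within each sex stratum (incl. pooled) plus
    every subgroup against the male/high-SES baseline.  Raw p-values only;
    BH gating is applied per model over the pooled set."""
    by_key = {(g.sex, g.ses): g for g in groups}
    contrasts: list[ContrastResult] = []

    def add(key_a, key_b):
        a, b = by_key.get(key_a), by_key.get(key_b)
        if a is None or b is None or a.replicates is None or b.replicates is None:
            return
        if key_a == key_b:
            contrasts.append(ContrastResult(key_a, key_b, 1.0))
            return
        contrasts.append(
            ContrastResult(key_a, key_b, compare_groups(a.replicates, b.replicates))
        )

    for sex in ("M", "F", "all"):
        add((sex, "low"), (sex, "high"))
    for key in [("M", "low"), ("F", "high"), ("F", "low")]:
        add(key, BASELINE_KEY)
    return contrasts


def apply_bh_and_directions(
    contrasts: list[ContrastResult],
    groups_by_measure: dict[str, list[SubgroupMetrics]],
    fdr: float = 0.05,
) -> None:
    """In-place BH gating over a pooled p-value family; direction flags are
    set only where the adjusted decision is significant."""
    if not contrasts:
        return
    reject = bh_adjust([c.raw_p for c in contrasts], fdr)
    lookup = {
        (measure, g.sex, g.ses): g
        for measure, groups in groups_by_measure.items()
        for g in groups
    }
    for c, rej in zip(contrasts, reject):
        c.significant = bool(rej)
        if not rej:
            c.direction = "none"
            continue
        a = lookup[(c.measure, *c.key_a)]
        b = lookup[(c.measure, *c.key_b)]
        diff = float(np.mean(a.replicates) - np.mean(b.replicates))
        c.direction = "higher" if diff > 0 else ("lower" if diff < 0 else "none")


def contrast_to_baseline(
    groups: list[SubgroupMetrics],
    contrasts: list[ContrastResult],
    baseline: tuple[str, str] = BASELINE_KEY,
) -> pd.DataFrame:
    """Baseline-flag table: Higher/Lower/none per subgroup vs the baseline,
    reported only where BH-adjusted significance holds."""
    if not any((g.sex, g.ses) == baseline for g in groups):
        raise ValueError(f"baseline subgroup {baseline} missing from metrics")
    flag_by_key = {}
    for c in contrasts:
        if c.key_b == baseline:
            flag_by_key[c.key_a] = c.direction if c.significant else "none"
    rows = []
    for g in groups:
        key = (g.sex, g.ses)
        if key == baseline:
            flag = "base"
        else:
            flag = flag_by_key.get(key, "none")
        rows.append({"sex": g.sex, "ses": g.ses, "flag": flag})
    return pd.DataFrame(rows)


def audit_predictions(
    pred: pd.DataFrame,
    measures: list[str],
    B: int = 1000,
    seed: int | None = None,
    fdr: float = 0.05,
) -> dict:
    """Full audit of one model's predictions: per-measure subgroup metrics,
    pairwise contrasts with per-model pooled BH control, baseline flags and
    pooled-sex relative BER differences."""
    groups_by_measure: dict[str, list[SubgroupMetrics]] = {}
    all_contrasts: list[ContrastResult] = []
    for j, measure in enumerate(measures):
        groups = subgroup_metrics(
            pred, measure, B=B, seed=None if seed is None else seed + 1000 * j
        )
        groups_by_measure[measure] = groups
        contrasts = pairwise_contrasts(groups)
        for c in contrasts:
            c.measure = measure
        all_contrasts.extend(contrasts)
    apply_bh_and_directions(all_contrasts, groups_by_measure, fdr)

    result: dict = {"measures": {}}
    for measure in measures:
        groups = groups_by_measure[measure]
        contrasts = [c for c in all_contrasts if c.measure == measure]
        pooled = {g.ses: g for g in groups if g.sex == "all"}
        rel = None
        if pooled.get("low") and pooled.get("high"):
            if pooled["low"].ber is not None and pooled["high"].ber not in (None, 0.0):
                rel = relative_ber_difference(pooled["low"].ber, pooled["high"].ber)
        result["measures"][measure] = {
            "metrics": metrics_table(groups),
            "contrasts": contrasts,
            "baseline_flags": contrast_to_baseline(groups, contrasts),
            "relative_ber_difference": rel,
        }
    return result
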