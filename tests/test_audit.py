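"""Unit and property tests for the subgroup error-metric machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairdem.audit import (
    BASELINE_KEY,
    ConfusionCounts,
    audit_predictions,
    balanced_error_rate,
    bh_adjust,
    bootstrap_ber,
    compare_groups,
    confusion,
    excess_misclassification,
    relative_ber_difference,
    subgroup_metrics,
)
from fairdem.exceptions import UndefinedMetricError

from conftest import make_predictions


def brute_force_ber(y_true, y_pred):
    """Independent oracle: average of the per-class mean error rates."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    errs = []
    for cls in (0, 1):
        mask = t == cls
        errs.append(np.mean(p[mask] != cls))
    return float(np.mean(errs))


def brute_force_bh(pvals, q=0.05):
    """Step-up definition: largest k with p_(k) <= k*q/m; reject the k
    smallest p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ks = np.nonzero(p[order] <= (np.arange(1, m + 1) * q / m))[0]
    reject = np.zeros(m, dtype=bool)
    if len(ks):
        reject[order[: ks.max() + 1]] = True
    return reject


class TestConfusion:
    @pytest.mark.parametrize(
        "t,p,expect",
        [
            ([1, 0], [1, 0], (1, 0, 1, 0)),
            ([1, 1, 0, 0], [0, 0, 1, 1], (0, 2, 0, 2)),
            ([], [], (0, 0, 0, 0)),
        ],
    )
    def test_counts(self, t, p, expect):
        c = confusion(t, p)
        assert (c.tp, c.fp, c.tn, c.fn) == expect
        assert c.total == len(t)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [0, 1])
        with pytest.raises(ValueError):
            confusion([0, 1], [0, 1, 1])


class TestBalancedErrorRate:
    def test_perfect_and_inverted(self):
        assert balanced_error_rate(confusion([1, 0], [1, 0])) == 0.0
        assert balanced_error_rate(confusion([1, 0], [0, 1])) == 1.0

    def test_forced_arithmetic(self):
        c = ConfusionCounts(tp=5, fp=3, tn=7, fn=5)
        assert balanced_error_rate(c) == pytest.approx(0.4)

    def test_missing_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            balanced_error_rate(confusion([1, 1], [1, 0]))

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 2**24 - 1))
    def test_matches_brute_force_enumeration(self, n, bits):
        rng = np.random.default_rng(bits)
        t = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        if len(np.unique(t)) < 2:
            t[0], t[1] = 0, 1
        assert balanced_error_rate(confusion(t, p)) == pytest.approx(
            brute_force_ber(t, p)
        )

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(4, 40), st.integers(0, 2**24 - 1))
    def test_extra_false_negative_never_decreases_ber(self, n, bits):
        rng = np.random.default_rng(bits)
        t = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        t[:2] = [0, 1]
        hits = np.nonzero((t == 1) & (p == 1))[0]
        if len(hits) == 0:
            return
        before = balanced_error_rate(confusion(t, p))
        p2 = p.copy()
        p2[hits[0]] = 0  # one more FN, all else fixed
        assert balanced_error_rate(confusion(t, p2)) >= before

    def test_pooled_ber_comes_from_pooled_counts(self):
        # deliberately asymmetric sexes: pooled metric must equal the
        # counts-based recomputation, not the mean of per-sex BERs
        pred = make_predictions(n=400, seed=4)
        pred.loc[pred["sex"] == "F", "y_pred"] ^= (
            np.random.default_rng(0).random((pred["sex"] == "F").sum()) < 0.3
        ).astype(int)
        groups = subgroup_metrics(pred, "m1", B=10, seed=0)
        pooled_low = next(g for g in groups if g.sex == "all" and g.ses == "low")
        mask = pred["ses_m1"] == "low"
        expect = balanced_error_rate(
            confusion(pred.loc[mask, "y_true"], pred.loc[mask, "y_pred"])
        )
        assert pooled_low.ber == pytest.approx(expect)
        per_sex = [g.ber for g in groups if g.sex in ("M", "F") and g.ses == "low"]
        assert pooled_low.ber != pytest.approx(np.mean(per_sex), abs=1e-12)


class TestBootstrap:
    def test_all_correct_degenerates_to_zero(self):
        y = np.array([1, 0] * 20)
        res = bootstrap_ber(y, y, B=100, seed=0)
        assert np.all(res.replicates == 0.0)
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_seeded_determinism(self):
        pred = make_predictions(n=200, seed=1)
        a = bootstrap_ber(pred["y_true"], pred["y_pred"], B=200, seed=42)
        b = bootstrap_ber(pred["y_true"], pred["y_pred"], B=200, seed=42)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_replicate_mean_tracks_point_estimate(self):
        pred = make_predictions(n=500, ber_low=0.3, ber_high=0.3, seed=2)
        point = balanced_error_rate(confusion(pred["y_true"], pred["y_pred"]))
        res = bootstrap_ber(pred["y_true"], pred["y_pred"], B=1000, seed=3)
        assert abs(res.replicates.mean() - point) < 0.03

    def test_single_class_sample_undefined(self):
        with pytest.raises(UndefinedMetricError):
            bootstrap_ber([1, 1, 1], [1, 0, 1], B=10, seed=0)


class TestCompareGroups:
    def test_identical_vectors(self):
        a = np.linspace(0.2, 0.4, 100)
        assert compare_groups(a, a) == pytest.approx(1.0)

    def test_separated_normals(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.30, 0.01, 1000)
        b = rng.normal(0.40, 0.01, 1000)
        assert compare_groups(a, b) < 1e-10

    def test_equal_means_unequal_variances(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.3, 0.001, 2000)
        b = rng.normal(0.3, 0.05, 2000)
        assert compare_groups(a, b) > 0.05

    def test_zero_variance_equal_means(self):
        assert compare_groups([0.3] * 10, [0.3] * 10) == 1.0


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "pvals,expect",
        [
            ([0.01], [True]),
            ([0.01, 0.02, 0.03, 0.04], [True] * 4),
            ([0.04, 0.90], [False, False]),
        ],
    )
    def test_examples(self, pvals, expect):
        assert bh_adjust(pvals).tolist() == expect

    def test_matches_step_up_definition_on_random_vectors(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            m = int(rng.integers(1, 25))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            np.testing.assert_array_equal(bh_adjust(p), brute_force_bh(p))

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0


class TestRelativeDifferenceAndBurden:
    def test_printed_cells(self):
        assert round(100 * relative_ber_difference(0.4617, 0.3925), 2) == 17.63
        assert round(100 * relative_ber_difference(0.3411, 0.3626), 2) == -5.93

    def test_parity_and_zero_denominator(self):
        assert relative_ber_difference(0.3, 0.3) == 0.0
        with pytest.raises(UndefinedMetricError):
            relative_ber_difference(0.1, 0.0)

    def test_excess_misclassification(self):
        assert excess_misclassification(0.393, 0.462, 1000) == 69
        assert excess_misclassification(0.25, 0.25, 1000) == 0
        assert excess_misclassification(0.0, 1.0, 250) == 250
        with pytest.raises(ValueError):
            excess_misclassification(0.1, 0.2, -5)


class TestSubgroupAudit:
    def test_strata_and_baseline_flags(self):
        pred = make_predictions(n=2000, ber_low=0.45, ber_high=0.15, seed=9)
        result = audit_predictions(pred, ["m1"], B=300, seed=1)
        tables = result["measures"]["m1"]
        metrics = tables["metrics"]
        assert len(metrics) == 6  # M/F/all x high/low
        flags = tables["baseline_flags"]
        base_row = flags[(flags.sex == BASELINE_KEY[0]) & (flags.ses == BASELINE_KEY[1])]
        assert base_row["flag"].item() == "base"
        # the strongly degraded low-SES male subgroup must flag higher
        male_low = flags[(flags.sex == "M") & (flags.ses == "low")]["flag"].item()
        assert male_low == "higher"
        assert tables["relative_ber_difference"] > 0

    def test_direction_none_without_significance(self):
        pred = make_predictions(n=300, ber_low=0.3, ber_high=0.3, seed=5)
        result = audit_predictions(pred, ["m1"], B=200, seed=2)
        for c in result["measures"]["m1"]["contrasts"]:
            if not c.significant:
                assert c.direction == "none"

    def test_degenerate_subgroup_reported_not_dropped(self):
        pred = make_predictions(n=120, seed=6)
        pred.loc[(pred.ses_m1 == "low") & (pred.sex == "M"), "y_true"] = 1
        groups = subgroup_metrics(pred, "m1", B=20, seed=0)
        low_m = next(g for g in groups if g.sex == "M" and g.ses == "low")
        assert low_m.ber is None
        assert low_m.note != ""
        assert low_m.counts.total > 0
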