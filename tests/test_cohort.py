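"""Tests for index assignment, SES dichotomization and eligibility filters."""

import numpy as np
import pandas as pd
import pytest

from fairdem.cohort import (
    EXCLUSION_REASONS,
    assign_case_index,
    build_cohort,
    dichotomize_ses,
    sample_control_index,
)
from fairdem.config import MeasureRule, SesDichotomyConfig, TimelineConfig
from fairdem.exceptions import MeasureRangeError
from fairdem.synthetic import generate_population
from fairdem.config import research_panel

from conftest import quick_population


def _patient(pid="p1", sex="M", birth="1940-01-01", first="2004-01-01",
             last="2020-12-31", onset=None):
    return {
        "patient_id": pid,
        "sex": sex,
        "birth_date": pd.Timestamp(birth),
        "first_record_date": pd.Timestamp(first),
        "last_record_date": pd.Timestamp(last),
        "dementia_onset_date": pd.Timestamp(onset) if onset else pd.NaT,
        "ses_m1": 50.0,
        "ses_m2": 10.0,
        "ses_m3": 2.0,
    }


class TestCaseIndex:
    def test_index_is_one_year_before_onset(self):
        m = assign_case_index(_patient(onset="2015-06-01"), TimelineConfig())
        assert m["index_date"] == pd.Timestamp("2014-06-01")
        assert m["eligible"]

    def test_age_below_minimum_excluded(self):
        m = assign_case_index(
            _patient(birth="1956-01-01", onset="2005-03-01"), TimelineConfig()
        )
        assert not m["eligible"]
        assert m["exclusion_reason"] == "age_lt_min"

    def test_empty_observation_window_excluded(self):
        m = assign_case_index(
            _patient(onset="2015-03-01"),
            TimelineConfig(),
            visit_dates=["2015-01-01", "2005-01-01"],  # none in [2009-03, 2014-03)
        )
        assert not m["eligible"]
        assert m["exclusion_reason"] == "no_observation_record"

    def test_missing_onset_rejected(self):
        with pytest.raises(ValueError):
            assign_case_index(_patient(), TimelineConfig())

    def test_leap_day_onset(self):
        m = assign_case_index(_patient(onset="2016-02-29"), TimelineConfig())
        assert m["index_date"] == pd.Timestamp("2015-02-28")


class TestDichotomize:
    def test_upper_range_rule(self):
        assert dichotomize_ses(80.0, "m2") is True
        assert dichotomize_ses(75.0, "m2") is False

    def test_decile_rule(self):
        assert dichotomize_ses(7, "m3") is False
        assert dichotomize_ses(8, "m3") is True

    def test_empirical_bottom_quartile(self):
        cfg = SesDichotomyConfig(
            rules={"m1": MeasureRule("bottom-quartile", (0.0, 100.0))}
        )
        values = pd.Series(np.arange(100, dtype=float))
        low = dichotomize_ses(values, "m1", cfg)
        assert low[values < 24.75].all() and not low[values >= 25].any()
        assert low.mean() == pytest.approx(0.25, abs=0.01)

    def test_out_of_range_names_measure(self):
        with pytest.raises(MeasureRangeError) as err:
            dichotomize_ses(140.0, "m2")
        assert "m2" in str(err.value)


class TestControlMatching:
    def test_single_bin_forced(self):
        controls = pd.DataFrame([_patient(pid="c1", birth="1930-01-01")])
        out = sample_control_index(controls, [80.0], TimelineConfig(), seed=0)
        assert out.loc[0, "eligible"]
        age = out.loc[0, "age_at_index"]
        assert 75 <= age < 85

    def test_insufficient_followup(self):
        controls = pd.DataFrame(
            [_patient(pid="c1", birth="1930-01-01", last="2009-06-30")]
        )
        out = sample_control_index(controls, [80.0], TimelineConfig(), seed=0)
        assert not out.loc[0, "eligible"]
        assert out.loc[0, "exclusion_reason"] == "insufficient_followup"

    def test_empty_control_table(self):
        out = sample_control_index(
            pd.DataFrame(columns=list(_patient().keys())), [80.0],
            TimelineConfig(), seed=0
        )
        assert len(out) == 0

    def test_age_histogram_matched(self):
        # case age-bin proportions 5% / 38% / 54% / 3% over 65-74 ... 95+
        rng = np.random.default_rng(5)
        bins = [(65, 75), (75, 85), (85, 95), (95, 100)]
        probs = [0.05, 0.38, 0.54, 0.03]
        which = rng.choice(4, size=2000, p=probs)
        case_ages = np.array([rng.uniform(*bins[w]) for w in which])
        n = 5000
        anchor = pd.Timestamp("2014-07-01")
        births = [
            anchor - pd.Timedelta(days=int(a * 365.25))
            for a in rng.choice(case_ages, size=n)
        ]
        controls = pd.DataFrame(
            [_patient(pid=f"c{i}", birth=b) for i, b in enumerate(births)]
        )
        out = sample_control_index(controls, case_ages, TimelineConfig(), seed=1)
        ok = out[out["eligible"]]
        assert len(ok) > 0.9 * n
        edges = np.array([45, 55, 65, 75, 85, 95, 105])
        p_case, _ = np.histogram(case_ages, bins=edges)
        p_ctrl, _ = np.histogram(ok["age_at_index"].astype(float), bins=edges)
        p_case = p_case / p_case.sum()
        p_ctrl = p_ctrl / p_ctrl.sum()
        mask = (p_case + p_ctrl) > 0
        chi2_dist = 0.5 * np.sum(
            (p_case[mask] - p_ctrl[mask]) ** 2 / (p_case[mask] + p_ctrl[mask])
        )
        assert chi2_dist < 0.01


class TestBuildCohort:
    def _toy_tables(self):
        patients = pd.DataFrame(
            [
                _patient("case_ok", onset="2013-05-01", birth="1932-01-01"),
                _patient("case_young", onset="2005-03-01", birth="1956-01-01"),
                _patient("case_ok2", onset="2016-09-01", birth="1935-06-01"),
                _patient("ctrl_ok1", birth="1933-01-01"),
                _patient("ctrl_ok2", birth="1934-01-01"),
                _patient("ctrl_ok3", birth="1930-01-01"),
                _patient("ctrl_ok4", birth="1931-01-01"),
                _patient("ctrl_short", birth="1932-01-01", last="2009-06-30"),
                _patient("ctrl_novisit", birth="1933-07-01"),
            ]
        )
        rows = []
        for pid in patients["patient_id"]:
            if pid == "ctrl_novisit":
                continue
            for year in range(2004, 2021):
                for month in (3, 9):
                    rows.append(
                        {"patient_id": pid,
                         "visit_date": pd.Timestamp(f"{year}-{month:02d}-15"),
                         "categories": "1"}
                    )
        return patients, pd.DataFrame(rows)

    def test_exclusion_ledger_counts_each_filter_once(self):
        patients, visits = self._toy_tables()
        cohort, ledger = build_cohort(patients, visits, seed=2)
        assert ledger == {
            "age_lt_min": 1,
            "insufficient_followup": 1,
            "no_observation_record": 1,
        }
        excluded = cohort[~cohort["eligible"]]
        assert (excluded["exclusion_reason"] != "").all()
        assert ledger_sums_match(cohort, ledger)

    def test_all_eligible_gives_zero_ledger(self):
        patients, visits = self._toy_tables()
        keep = ~patients["patient_id"].isin(
            ["case_young", "ctrl_short", "ctrl_novisit"]
        )
        cohort, ledger = build_cohort(patients[keep], visits, seed=2)
        assert all(v == 0 for v in ledger.values())
        assert cohort["eligible"].all()

    def test_row_level_eligibility_invariants(self, small_run):
        _, patients, visits, cohort, ledger = small_run
        assert ledger_sums_match(cohort, ledger)
        elig = cohort[cohort["eligible"]]
        # every eligible member has >= 1 visit in the observation window
        from fairdem.features import visit_year_offsets

        covered = set(visit_year_offsets(elig, visits)["patient_id"])
        assert set(elig["patient_id"]) <= covered
        # eligible controls keep >= 1 year of follow-up
        ctrl = elig[elig["label"] == 0].merge(
            patients[["patient_id", "last_record_date"]], on="patient_id"
        )
        followup = (ctrl["last_record_date"] - ctrl["index_date"]).dt.days
        assert (followup >= 365).all()

    def test_seeded_determinism(self, small_run):
        _, patients, visits, cohort, _ = small_run
        again, _ = build_cohort(patients, visits, seed=5)
        pd.testing.assert_frame_equal(cohort, again)

    def test_case_share_recovered_research_panel(self):
        cfg = research_panel(n_patients=3000, seed=21)
        patients, visits = generate_population(cfg)
        cohort, _ = build_cohort(patients, visits, seed=22)
        share = cohort.loc[cohort["eligible"], "label"].mean()
        assert abs(share - 0.223) < 0.03

    def test_control_case_ratio_downsampling(self, small_run):
        _, patients, visits, _, _ = small_run
        timeline = TimelineConfig(control_case_ratio=1.0)
        cohort, ledger = build_cohort(patients, visits, timeline, seed=5)
        elig = cohort[cohort["eligible"]]
        n_cases = int((elig["label"] == 1).sum())
        n_ctrl = int((elig["label"] == 0).sum())
        assert abs(n_ctrl - n_cases) <= 1
        assert ledger.get("not_sampled", 0) > 0


def ledger_sums_match(cohort, ledger):
    core = {k: v for k, v in ledger.items() if k in EXCLUSION_REASONS}
    return sum(core.values()) == int((~cohort["eligible"]).sum())
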