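import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import entry
from daakidney import (KidneyCategory, baseline_egfr, build_daily_egfr,
                       categorize, egfr_from_scre, follow_up)
from daakidney.exposure import TreatmentEpisode, ExposurePattern
from oracles import egfr_oracle, follow_up_oracle

T0 = pd.Timestamp("2015-06-01")


def _d(offset):
    return T0 + pd.Timedelta(days=offset)


class TestEgfrFormula:
    @pytest.mark.parametrize("scre, age, sex, expected", [
        (1.0, 60, "male", 59.90627572732373),
        (1.0, 60, "female", 44.27073776249224),
        (2.0, 60, "male", 28.063737265591303),
    ])
    def test_frozen_log_space_values(self, scre, age, sex, expected):
        assert egfr_from_scre(scre, age, sex) == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(scre=st.floats(0.2, 15.0), age=st.floats(18.0, 100.0))
    def test_matches_log_space_oracle_and_sex_ratio(self, scre, age):
        male = egfr_from_scre(scre, age, "male")
        female = egfr_from_scre(scre, age, "female")
        assert male == pytest.approx(egfr_oracle(scre, age, False), rel=1e-9)
        assert female == pytest.approx(egfr_oracle(scre, age, True), rel=1e-9)
        assert female / male == pytest.approx(0.739, rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(scre=st.floats(0.2, 10.0), age=st.floats(20.0, 90.0),
           bump=st.floats(0.01, 2.0))
    def test_strictly_decreasing_in_scre_and_age(self, scre, age, bump):
        for sex in ("male", "female"):
            base = egfr_from_scre(scre, age, sex)
            assert egfr_from_scre(scre + bump, age, sex) < base
            assert egfr_from_scre(scre, age + bump, sex) < base

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            egfr_from_scre(0.0, 60, "male")
        with pytest.raises(ValueError):
            egfr_from_scre(1.0, -1, "male")


class TestCategories:
    @pytest.mark.parametrize("boundary, better, worse", [
        (90.0, KidneyCategory.NORMAL, KidneyCategory.MILD),
        (60.0, KidneyCategory.MILD, KidneyCategory.MILD_MODERATE),
        (45.0, KidneyCategory.MILD_MODERATE, KidneyCategory.MODERATE_SEVERE),
        (30.0, KidneyCategory.MODERATE_SEVERE, KidneyCategory.SEVERE),
        (15.0, KidneyCategory.SEVERE, KidneyCategory.FAILURE),
    ])
    def test_lower_bounds_are_inclusive(self, boundary, better, worse):
        assert categorize(boundary) is better
        assert categorize(np.nextafter(boundary, 0.0)) is worse

    def test_examples(self):
        assert categorize(89.999) is KidneyCategory.MILD
        assert categorize(14.999) is KidneyCategory.FAILURE
        with pytest.raises(ValueError):
            categorize(0.0)


def _patients(pid="X", sex="male", birth="1955-01-01"):
    return pd.DataFrame({"patient_id": [pid], "sex": [sex],
                         "birth_date": [pd.Timestamp(birth)]})


def _labs(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "date", "analyte", "value"])
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


class TestDailyEgfr:
    def test_same_day_values_average(self):
        daily = build_daily_egfr(_labs([("X", _d(0), "eGFR", 70.0),
                                        ("X", _d(0), "eGFR", 80.0)]), _patients())
        assert len(daily) == 1
        assert daily.loc[0, "value"] == 75.0
        assert daily.loc[0, "source"] == "mean_of_multiple"

    def test_scre_fallback_uses_completed_years_at_lab_date(self):
        # age 60 completed years on 2015-06-01 for birth 1955-01-01
        daily = build_daily_egfr(_labs([("X", _d(0), "sCRE", 1.0)]), _patients())
        assert daily.loc[0, "source"] == "converted_from_sCRE"
        assert daily.loc[0, "value"] == pytest.approx(59.90627572732373, rel=1e-9)
        # one day before the 60th birthday the completed age is still 59
        daily_before = build_daily_egfr(
            _labs([("X", "2014-12-31", "sCRE", 1.0)]), _patients())
        assert daily_before.loc[0, "value"] == pytest.approx(
            egfr_oracle(1.0, 59, False), rel=1e-9)

    def test_recorded_egfr_takes_precedence_over_scre(self):
        daily = build_daily_egfr(_labs([("X", _d(0), "eGFR", 70.0),
                                        ("X", _d(0), "sCRE", 2.0)]), _patients())
        assert len(daily) == 1
        assert daily.loc[0, "value"] == 70.0
        assert daily.loc[0, "source"] == "recorded"


class TestBaseline:
    def test_latest_value_in_window_wins(self):
        daily = build_daily_egfr(_labs([("X", _d(-40), "eGFR", 80.0),
                                        ("X", _d(-5), "eGFR", 72.0)]), _patients())
        value, cat = baseline_egfr(entry(), daily)
        assert value == 72.0 and cat is KidneyCategory.MILD

    def test_window_boundary_t0_minus_90_included(self):
        daily = build_daily_egfr(_labs([("X", _d(-90), "eGFR", 66.0)]), _patients())
        value, _ = baseline_egfr(entry(), daily)
        assert value == 66.0

    def test_t0_day_value_never_used(self):
        daily = build_daily_egfr(_labs([("X", _d(0), "eGFR", 50.0),
                                        ("X", _d(-10), "eGFR", 75.0)]), _patients())
        value, _ = baseline_egfr(entry(), daily)
        assert value == 75.0

    def test_missing_baseline_raises(self):
        daily = build_daily_egfr(_labs([("X", _d(-120), "eGFR", 75.0)]), _patients())
        with pytest.raises(ValueError, match="no kidney-function value"):
            baseline_egfr(entry(), daily)


def _episode(end_offset, truncated=False):
    return TreatmentEpisode(
        patient_id="X", pattern=ExposurePattern.P7_LDV_SOF, start=T0,
        supply_end=_d(end_offset - 7), end=_d(end_offset),
        truncated=truncated, n_prescriptions=1)


STUDY_END = pd.Timestamp("2017-12-31")


class TestFollowUp:
    def _daily(self, series):
        return build_daily_egfr(
            _labs([("X", _d(off), "eGFR", val) for off, val in series]
                  + [("X", _d(-14), "eGFR", 74.0)]), _patients())

    def test_one_category_drop_detected_at_first_crossing_day(self):
        daily = self._daily([(10, 65.0), (20, 59.0)])
        fu = follow_up(entry(), "P7", _episode(60), daily, None, STUDY_END, 1)
        assert fu.outcome == "event" and fu.person_days == 20
        assert fu.end_reason == "outcome"

    def test_two_category_threshold_censors_same_series(self):
        daily = self._daily([(10, 65.0), (20, 59.0)])
        fu = follow_up(entry(), "P7", _episode(60), daily, None, STUDY_END, 2)
        assert fu.outcome == "censored" and fu.end_reason == "treatment_end"
        assert fu.person_days == 60

    def test_t0_day_drop_is_not_an_event(self):
        daily = build_daily_egfr(
            _labs([("X", _d(-14), "eGFR", 74.0), ("X", _d(0), "eGFR", 50.0),
                   ("X", _d(30), "eGFR", 73.0)]), _patients())
        fu = follow_up(entry(), "P7", _episode(60), daily, None, STUDY_END, 1)
        assert fu.outcome == "censored"

    def test_pattern_change_censors_day_before(self):
        daily = self._daily([(10, 70.0)])
        fu = follow_up(entry(), "P7", _episode(60), daily, _d(30), STUDY_END, 1)
        assert fu.end_reason == "pattern_change" and fu.person_days == 29

    def test_event_beats_same_day_censoring(self):
        daily = self._daily([(60, 59.0)])
        fu = follow_up(entry(), "P7", _episode(60), daily, None, STUDY_END, 1)
        assert fu.outcome == "event" and fu.person_days == 60

    def test_zero_person_days_when_change_on_day_after_t0(self):
        daily = self._daily([(10, 70.0)])
        fu = follow_up(entry(), "P7", _episode(60), daily, _d(1), STUDY_END, 1)
        assert fu.person_days == 0 and fu.outcome == "censored"


@settings(deadline=None, max_examples=150)
@given(data=st.data())
def test_follow_up_matches_day_enumeration_oracle(data):
    """Randomised patients: follow-up equals the day-by-day oracle and the
    two-category events nest inside the one-category events."""
    rng_vals = data.draw(st.lists(
        st.tuples(st.integers(1, 120), st.floats(10.0, 120.0)),
        min_size=0, max_size=8, unique_by=lambda t: t[0]))
    episode_end = data.draw(st.integers(0, 100))
    truncated = data.draw(st.booleans())
    change = data.draw(st.one_of(st.none(), st.integers(1, 110)))
    baseline_value = data.draw(st.floats(46.0, 110.0))

    labs = [("X", _d(-7), "eGFR", baseline_value)]
    labs += [("X", _d(off), "eGFR", val) for off, val in rng_vals]
    daily = build_daily_egfr(_labs(labs), _patients())
    study_end_off = 119 if truncated else 365
    study_end = _d(study_end_off)
    episode = _episode(min(episode_end, study_end_off),
                       truncated=truncated and episode_end >= study_end_off)
    change_ts = _d(change) if change is not None else None

    results = {}
    for thr in (1, 2):
        fu = follow_up(entry(), "P7", episode, daily, change_ts, study_end, thr)
        expected = follow_up_oracle(
            0, (episode.end - T0).days, episode.truncated,
            change, study_end_off,
            {off: val for off, val in rng_vals},
            int(categorize(baseline_value)),
            lambda v: int(categorize(v)), thr)
        assert (fu.outcome, (fu.end_date - T0).days, fu.end_reason,
                fu.person_days) == expected
        results[thr] = fu
    if results[2].outcome == "event":
        assert results[1].outcome == "event"
        assert results[2].end_date >= results[1].end_date
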