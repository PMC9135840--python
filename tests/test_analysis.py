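import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from daakidney import (compare_baseline, incidence_rate, mask_small_cells,
                       person_years, rate_ratio)
from daakidney.analysis import mask_count
from oracles import exact_irr_oracle


class TestPersonTime:
    def test_days_over_365_25(self):
        assert person_years(365) == pytest.approx(365 / 365.25)
        assert person_years(87) == pytest.approx(0.23819301848049282)

    def test_zero_days_is_exactly_zero(self):
        assert person_years(0) == 0.0

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            person_years(-1)

    def test_incidence_rate(self):
        assert incidence_rate(0, 10.0) == 0.0
        assert incidence_rate(10, 2.0) == 5.0
        assert math.isnan(incidence_rate(3, 0.0))
        with pytest.raises(ValueError):
            incidence_rate(-1, 1.0)


class TestRateRatio:
    def test_point_estimate(self):
        rr = rate_ratio((10, 2.0), (5, 4.0))
        assert rr["irr"] == pytest.approx(4.0)

    def test_zero_numerator_gives_zero_irr_finite_upper_bound(self):
        rr = rate_ratio((0, 2.0), (5, 4.0))
        assert rr["irr"] == 0.0
        assert rr["ci_low"] == 0.0
        assert np.isfinite(rr["ci_high"]) and rr["ci_high"] > 0

    def test_zero_control_events_reports_infinite_point(self):
        rr = rate_ratio((3, 2.0), (0, 4.0))
        assert math.isinf(rr["irr"])
        assert rr["ci_low"] > 0

    def test_frozen_example_against_enumeration_oracle(self):
        rr = rate_ratio((8, 1.0), (2, 4.0))
        p, lo, hi = exact_irr_oracle(8, 1.0, 2, 4.0)
        assert rr["irr"] == pytest.approx(16.0)
        assert rr["p_value"] == pytest.approx(p, rel=1e-9)
        assert rr["ci_low"] == pytest.approx(lo, rel=1e-6)
        assert rr["ci_high"] == pytest.approx(hi, rel=1e-6)

    @settings(deadline=None, max_examples=120)
    @given(x_e=st.integers(0, 25), x_c=st.integers(0, 25),
           py_e=st.floats(0.5, 50.0), py_c=st.floats(0.5, 50.0))
    def test_matches_scipy_binomtest_and_oracle(self, x_e, x_c, py_e, py_c):
        if x_e + x_c == 0:
            return
        rr = rate_ratio((x_e, py_e), (x_c, py_c))
        p0 = py_e / (py_e + py_c)
        scipy_p = stats.binomtest(x_e, x_e + x_c, p0).pvalue
        assert rr["p_value"] == pytest.approx(float(scipy_p), rel=1e-8, abs=1e-12)
        p, lo, hi = exact_irr_oracle(x_e, py_e, x_c, py_c)
        assert rr["p_value"] == pytest.approx(p, rel=1e-8, abs=1e-12)
        assert rr["ci_low"] == pytest.approx(lo, rel=1e-5, abs=1e-9)
        if math.isinf(hi):
            assert math.isinf(rr["ci_high"])
        else:
            assert rr["ci_high"] == pytest.approx(hi, rel=1e-5)

    @settings(deadline=None, max_examples=60)
    @given(x_e=st.integers(0, 15), x_c=st.integers(1, 15),
           scale=st.floats(0.01, 100.0))
    def test_scale_invariance_of_person_time(self, x_e, x_c, scale):
        base = rate_ratio((x_e, 2.0), (x_c, 3.0))
        scaled = rate_ratio((x_e, 2.0 * scale), (x_c, 3.0 * scale))
        for key in ("irr", "ci_low", "ci_high", "p_value"):
            if isinstance(base[key], float) and math.isnan(base[key]):
                assert math.isnan(scaled[key])
            else:
                assert scaled[key] == pytest.approx(base[key], rel=1e-9)

    def test_wald_interval_close_to_exact_at_large_counts(self):
        exact = rate_ratio((80, 10.0), (40, 10.0))
        wald = rate_ratio((80, 10.0), (40, 10.0), method="wald")
        assert wald["irr"] == exact["irr"]
        assert wald["ci_low"] == pytest.approx(exact["ci_low"], rel=0.15)
        assert wald["ci_high"] == pytest.approx(exact["ci_high"], rel=0.15)


def _cohort_frame(rows):
    return pd.DataFrame(rows, columns=["pattern", "age_at_t0", "sex",
                                       "baseline_egfr"])


class TestBaselineComparison:
    def test_identical_groups_give_p_one(self):
        rows = [("P7", a, s, e) for a, s, e in
                [(50, "female", 70.0), (60, "male", 80.0), (70, "male", 90.0)]]
        rows += [("P5", a, s, e) for _, a, s, e in
                 [(0, 50, "female", 70.0), (0, 60, "male", 80.0),
                  (0, 70, "male", 90.0)]]
        comps = compare_baseline(_cohort_frame(rows))
        p5 = next(c for c in comps if c.pattern.value == "P5")
        assert p5.p_sex == pytest.approx(1.0)
        assert p5.p_age == pytest.approx(1.0, abs=0.05)

    def test_sex_test_matches_hypergeometric_for_equal_proportions(self):
        # 2x2 table [[3, 7], [30, 70]]: identical proportions, exact p = 1
        rows = [("P5", 60, "female", 75.0)] * 3 + [("P5", 60, "male", 75.0)] * 7
        rows += [("P7", 60, "female", 75.0)] * 30 + [("P7", 60, "male", 75.0)] * 70
        comps = compare_baseline(_cohort_frame(rows))
        p5 = next(c for c in comps if c.pattern.value == "P5")
        assert p5.p_sex == pytest.approx(1.0)
        assert p5.n_female == 3 and p5.pct_female == pytest.approx(30.0)

    def test_empty_pattern_omitted_and_missing_control_raises(self):
        rows = [("P7", 60, "male", 75.0)] * 3
        comps = compare_baseline(_cohort_frame(rows))
        assert [c.pattern.value for c in comps] == ["P7"]
        with pytest.raises(ValueError, match="control"):
            compare_baseline(_cohort_frame([("P5", 60, "male", 75.0)]))

    def test_medians_and_iqr(self):
        rows = [("P7", a, "male", e) for a, e in
                zip([40, 50, 60, 70, 80], [60.0, 65.0, 70.0, 75.0, 80.0])]
        comp = compare_baseline(_cohort_frame(rows))[0]
        assert comp.median_age == 60 and comp.median_egfr == 70.0
        assert comp.age_iqr == (50, 70)


class TestMasking:
    def test_count_just_below_threshold_masks(self):
        assert mask_count(9) == "< 10"
        assert mask_count(10) == "10"
        assert mask_count(0) == "< 10"

    def test_dependent_percentage_becomes_na(self):
        report = pd.DataFrame({
            "pattern": ["P4", "P7"], "n_patients": [9, 220],
            "n_female": [9, 127], "pct_female": [100.0, 57.7]})
        masked = mask_small_cells(report)
        assert masked.loc[0, "n_patients"] == "< 10"
        assert masked.loc[0, "n_female"] == "< 10"
        assert masked.loc[0, "pct_female"] == "NA"
        assert masked.loc[1, "n_patients"] == "220"
        assert masked.loc[1, "pct_female"] == 57.7
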