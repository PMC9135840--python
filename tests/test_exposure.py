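import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import entry
from daakidney import (ExposurePattern, build_treatment_episode,
                       classify_pattern, detect_pattern_change)
from daakidney.exposure import (REASON_MISSING_CONCOMITANT,
                                REASON_UNRECOGNIZED_ANCHOR,
                                ClassificationError)
from oracles import era_oracle

T0 = pd.Timestamp("2015-06-01")
STUDY_END = pd.Timestamp("2017-12-31")


def _rx(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "drug", "start_date",
                                        "days_supply"])
    frame["start_date"] = pd.to_datetime(frame["start_date"])
    return frame


def _d(offset):
    return T0 + pd.Timedelta(days=offset)


class TestClassification:
    def test_telaprevir_triple_therapy(self):
        rx = _rx([("X", "TVR", _d(0), 28), ("X", "PEG_IFN", _d(5), 28),
                  ("X", "RIB", _d(-3), 28)])
        pattern, reason = classify_pattern(entry(daas=("TVR",)), rx)
        assert pattern is ExposurePattern.P1_TVR_PEGIFN_RIB and reason is None

    def test_telaprevir_without_partners_is_unclassifiable(self):
        rx = _rx([("X", "TVR", _d(0), 28), ("X", "RIB", _d(0), 28)])
        pattern, reason = classify_pattern(entry(daas=("TVR",)), rx)
        assert pattern is None and reason == REASON_MISSING_CONCOMITANT

    def test_dcv_asv_pair_is_not_multiple_daas(self):
        rx = _rx([("X", "DCV", _d(0), 28), ("X", "ASV", _d(0), 28)])
        pattern, _ = classify_pattern(entry(daas=("DCV", "ASV")), rx)
        assert pattern is ExposurePattern.P3_DCV_ASV

    def test_dcv_alone_without_asv_feeds_criterion_six(self):
        rx = _rx([("X", "DCV", _d(0), 28)])
        pattern, reason = classify_pattern(entry(daas=("DCV",)), rx)
        assert pattern is None and reason == REASON_MISSING_CONCOMITANT

    @pytest.mark.parametrize("rib_offset, expected", [
        (30, ExposurePattern.P9_OBV_PTV_R_RIB),
        (-30, ExposurePattern.P9_OBV_PTV_R_RIB),
        (31, ExposurePattern.P8_OBV_PTV_R),
        (-31, ExposurePattern.P8_OBV_PTV_R),
    ])
    def test_ribavirin_window_boundary_splits_p8_p9(self, rib_offset, expected):
        rx = _rx([("X", "OBV_PTV_r", _d(0), 28), ("X", "RIB", _d(rib_offset), 28)])
        pattern, _ = classify_pattern(entry(daas=("OBV_PTV_r",)), rx)
        assert pattern is expected

    def test_removing_rib_reclassifies_p9_to_p8(self):
        rx = _rx([("X", "OBV_PTV_r", _d(0), 28), ("X", "RIB", _d(10), 28)])
        p_with, _ = classify_pattern(entry(daas=("OBV_PTV_r",)), rx)
        p_without, _ = classify_pattern(entry(daas=("OBV_PTV_r",)),
                                        rx[rx["drug"] != "RIB"])
        assert p_with is ExposurePattern.P9_OBV_PTV_R_RIB
        assert p_without is ExposurePattern.P8_OBV_PTV_R

    def test_every_pattern_is_reachable_and_control_unique(self, tiny):
        dataset, truth = tiny
        controls = [p for p in ExposurePattern if p.is_control]
        assert controls == [ExposurePattern.P7_LDV_SOF]
        assert set(truth["expected_pattern"]) == {p.value for p in ExposurePattern}


class TestEpisode:
    def test_single_prescription_grace(self):
        rx = _rx([("X", "LDV_SOF", _d(0), 14)])
        ep = build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     STUDY_END)
        assert (ep.supply_end - T0).days == 13
        assert (ep.end - T0).days == 20 and not ep.truncated

    def test_gap_of_exactly_28_days_merges(self):
        rx = _rx([("X", "LDV_SOF", _d(0), 14), ("X", "LDV_SOF", _d(41), 14)])
        ep = build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     STUDY_END)
        assert (ep.end - T0).days == 61

    def test_gap_of_29_days_ends_the_first_era(self):
        rx = _rx([("X", "LDV_SOF", _d(0), 14), ("X", "LDV_SOF", _d(42), 14)])
        ep = build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     STUDY_END)
        assert (ep.end - T0).days == 20

    def test_asunaprevir_follows_daclatasvir_era(self):
        # ASV supplied for 84 days, DCV for 28: the DCV era rules
        rx = _rx([("X", "DCV", _d(0), 28), ("X", "ASV", _d(0), 84)])
        ep = build_treatment_episode(entry(daas=("DCV", "ASV")),
                                     ExposurePattern.P3_DCV_ASV, rx, STUDY_END)
        assert (ep.supply_end - T0).days == 27

    def test_truncation_at_study_end(self):
        rx = _rx([("X", "LDV_SOF", STUDY_END - pd.Timedelta(days=5), 28)])
        ep = build_treatment_episode(
            entry(t0=STUDY_END - pd.Timedelta(days=5)),
            ExposurePattern.P7_LDV_SOF, rx, STUDY_END)
        assert ep.end == STUDY_END and ep.truncated

    def test_no_anchor_prescription_is_an_error(self):
        rx = _rx([("X", "RIB", _d(0), 28)])
        with pytest.raises(ClassificationError):
            build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                    STUDY_END)


@settings(deadline=None, max_examples=300)
@given(rx_spec=st.lists(st.tuples(st.integers(0, 150), st.integers(1, 60)),
                        min_size=1, max_size=8))
def test_episode_equals_day_coverage_oracle(rx_spec):
    """Era construction equals marking supply days, bridging gaps <= 28 and
    appending 7 grace days, on random prescription sets."""
    rx_spec = sorted(rx_spec)
    if rx_spec[0][0] != 0:
        rx_spec[0] = (0, rx_spec[0][1])  # anchor the first prescription at t0
    rx = _rx([("X", "LDV_SOF", _d(s), n) for s, n in rx_spec])
    ep = build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                 pd.Timestamp("2030-01-01"))
    start, end = era_oracle(rx_spec)
    assert start == 0
    assert (ep.end - T0).days == end


class TestPatternChange:
    def test_no_foreign_daa_means_no_change(self):
        rx = _rx([("X", "LDV_SOF", _d(0), 28), ("X", "RIB", _d(10), 28)])
        ep = build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     STUDY_END)
        assert detect_pattern_change(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     ep) is None

    def test_foreign_daa_inside_episode_changes(self):
        rx = _rx([("X", "LDV_SOF", _d(0), 28), ("X", "OBV_PTV_r", _d(30), 28)])
        ep = build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     STUDY_END)
        change = detect_pattern_change(entry(), ExposurePattern.P7_LDV_SOF, rx, ep)
        assert change == _d(30)

    def test_foreign_daa_after_episode_end_is_ignored(self):
        rx = _rx([("X", "LDV_SOF", _d(0), 14), ("X", "OBV_PTV_r", _d(60), 28)])
        ep = build_treatment_episode(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     STUDY_END)
        assert (ep.end - T0).days == 20
        assert detect_pattern_change(entry(), ExposurePattern.P7_LDV_SOF, rx,
                                     ep) is None

    def test_partner_drug_is_not_a_change_for_p3(self):
        rx = _rx([("X", "DCV", _d(0), 28), ("X", "ASV", _d(14), 28)])
        ep = build_treatment_episode(entry(daas=("DCV", "ASV")),
                                     ExposurePattern.P3_DCV_ASV, rx, STUDY_END)
        assert detect_pattern_change(entry(daas=("DCV", "ASV")),
                                     ExposurePattern.P3_DCV_ASV, rx, ep) is None
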