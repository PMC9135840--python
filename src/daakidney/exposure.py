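"""Exposure classification and treatment-episode (drug-era) construction.

Exposure groups are the ten prescription patterns defined by the anchor
direct-acting antiviral(s) dispensed on the index date t0 plus the
concomitant drugs required by each product's package insert, looked for
within 30 days before and after t0 (both ends inclusive):

    P1  TVR + Peg-IFN + Rib        P6  EBV + GZR
    P2  SMV + Peg-IFN + Rib        P7  LDV/SOF            (control)
    P3  DCV + ASV                  P8  OBV/PTV/r
    P4  VAN + Peg-IFN + Rib        P9  OBV/PTV/r + Rib
    P5  SOF + Rib                  P10 DCV/ASV/BCV

Patterns 8 and 9 share the anchor combination product and are distinguished
solely by ribavirin in the concomitancy window.  Time-at-risk is the drug
era built from the anchor prescriptions: supply intervals are stitched
together across gaps of at most 28 days and the final supply is extended by
a 7-day grace period.  Asunaprevir and grazoprevir follow the era of their
mandatory partner (daclatasvir and elbasvir respectively), so patterns 3 and
6 build the era from the partner drug alone.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

import pandas as pd

from .ehr import TARGET_DAAS

#: Concomitancy lookup window half-width around t0, days, both ends inclusive.
CONCOMITANCY_WINDOW_DAYS = 30
#: Maximum gap (days) between a merged supply end and the next start.
ERA_GAP_DAYS = 28
#: Grace period (days) appended once at the era end.
ERA_GRACE_DAYS = 7


class ClassificationError(ValueError):
    """Internal consistency failure while classifying or building episodes."""


@dataclasses.dataclass(frozen=True)
class _PatternSpec:
    label: str
    anchor: frozenset[str]            # DAA codes defining the pattern at/around t0
    required_concomitants: frozenset[str]  # non-anchor drugs required in the window
    episode_drugs: frozenset[str]     # drugs whose prescriptions define the era
    forbidden_concomitants: frozenset[str] = frozenset()
    is_control: bool = False


class ExposurePattern(str, enum.Enum):
    """The ten prescription patterns; values are the short codes used in tables."""

    P1_TVR_PEGIFN_RIB = "P1"
    P2_SMV_PEGIFN_RIB = "P2"
    P3_DCV_ASV = "P3"
    P4_VAN_PEGIFN_RIB = "P4"
    P5_SOF_RIB = "P5"
    P6_EBV_GZR = "P6"
    P7_LDV_SOF = "P7"
    P8_OBV_PTV_R = "P8"
    P9_OBV_PTV_R_RIB = "P9"
    P10_DCV_ASV_BCV = "P10"

    @property
    def spec(self) -> _PatternSpec:
        return _PATTERN_SPECS[self]

    @property
    def label(self) -> str:
        return self.spec.label

    @property
    def anchor(self) -> frozenset[str]:
        return self.spec.anchor

    @property
    def required_concomitants(self) -> frozenset[str]:
        return self.spec.required_concomitants

    @property
    def episode_drugs(self) -> frozenset[str]:
        return self.spec.episode_drugs

    @property
    def is_control(self) -> bool:
        return self.spec.is_control


_PATTERN_SPECS: dict[ExposurePattern, _PatternSpec] = {
    ExposurePattern.P1_TVR_PEGIFN_RIB: _PatternSpec(
        "TVR + Peg-IFN + Rib", frozenset({"TVR"}), frozenset({"PEG_IFN", "RIB"}),
        frozenset({"TVR"})),
    ExposurePattern.P2_SMV_PEGIFN_RIB: _PatternSpec(
        "SMV + Peg-IFN + Rib", frozenset({"SMV"}), frozenset({"PEG_IFN", "RIB"}),
        frozenset({"SMV"})),
    ExposurePattern.P3_DCV_ASV: _PatternSpec(
        # asunaprevir's era follows daclatasvir's, so DCV alone defines the era
        "DCV + ASV", frozenset({"DCV", "ASV"}), frozenset(), frozenset({"DCV"})),
    ExposurePattern.P4_VAN_PEGIFN_RIB: _PatternSpec(
        "VAN + Peg-IFN + Rib", frozenset({"VAN"}), frozenset({"PEG_IFN", "RIB"}),
        frozenset({"VAN"})),
    ExposurePattern.P5_SOF_RIB: _PatternSpec(
        "SOF + Rib", frozenset({"SOF"}), frozenset({"RIB"}), frozenset({"SOF"})),
    ExposurePattern.P6_EBV_GZR: _PatternSpec(
        # grazoprevir's era follows elbasvir's
        "EBV + GZR", frozenset({"EBV", "GZR"}), frozenset(), frozenset({"EBV"})),
    ExposurePattern.P7_LDV_SOF: _PatternSpec(
        "LDV/SOF", frozenset({"LDV_SOF"}), frozenset(), frozenset({"LDV_SOF"}),
        is_control=True),
    ExposurePattern.P8_OBV_PTV_R: _PatternSpec(
        "OBV/PTV/r", frozenset({"OBV_PTV_r"}), frozenset(), frozenset({"OBV_PTV_r"}),
        forbidden_concomitants=frozenset({"RIB"})),
    ExposurePattern.P9_OBV_PTV_R_RIB: _PatternSpec(
        "OBV/PTV/r + Rib", frozenset({"OBV_PTV_r"}), frozenset({"RIB"}),
        frozenset({"OBV_PTV_r"})),
    ExposurePattern.P10_DCV_ASV_BCV: _PatternSpec(
        # zero patients carried this pattern in the source cohort; kept for completeness
        "DCV/ASV/BCV", frozenset({"DCV_ASV_BCV"}), frozenset(),
        frozenset({"DCV_ASV_BCV"})),
}

CONTROL_PATTERN = ExposurePattern.P7_LDV_SOF

#: Multi-DAA sets on t0 permitted by the package inserts.
PERMITTED_DAA_COMBINATIONS = (frozenset({"GZR", "EBV"}), frozenset({"DCV", "ASV"}))

#: Classification failure reason codes.
REASON_MISSING_CONCOMITANT = "missing_required_concomitant"
REASON_UNRECOGNIZED_ANCHOR = "unrecognized_anchor_set"


@dataclasses.dataclass
class TreatmentEpisode:
    """A merged anchor-drug era defining time-at-risk from t0.

    ``supply_end`` is the last day covered by merged supplies; ``end`` adds
    the grace period, truncated at study end (``truncated`` records whether
    truncation occurred).
    """

    patient_id: str
    pattern: ExposurePattern
    start: pd.Timestamp
    supply_end: pd.Timestamp
    end: pd.Timestamp
    truncated: bool
    n_prescriptions: int


def _window_drugs(rx: pd.DataFrame, t0: pd.Timestamp) -> set[str]:
    lo = t0 - pd.Timedelta(days=CONCOMITANCY_WINDOW_DAYS)
    hi = t0 + pd.Timedelta(days=CONCOMITANCY_WINDOW_DAYS)
    mask = (rx["start_date"] >= lo) & (rx["start_date"] <= hi)
    return set(rx.loc[mask, "drug"])


def classify_drug_sets(
    anchor: frozenset[str], window_drugs: set[str]
) -> tuple[Optional[ExposurePattern], Optional[str]]:
    """Pattern decision from the t0 DAA set and the +-30-day window drug set."""
    if anchor == frozenset({"OBV_PTV_r"}):
        if "RIB" in window_drugs:
            return ExposurePattern.P9_OBV_PTV_R_RIB, None
        return ExposurePattern.P8_OBV_PTV_R, None
    for pattern in ExposurePattern:
        if pattern in (ExposurePattern.P8_OBV_PTV_R, ExposurePattern.P9_OBV_PTV_R_RIB):
            continue
        spec = pattern.spec
        if anchor <= spec.anchor:
            # a mandatory partner DAA (P3/P6) may be dispensed within the
            # window rather than on t0 itself
            if not spec.anchor <= (window_drugs | anchor):
                return None, REASON_MISSING_CONCOMITANT
            if not spec.required_concomitants <= window_drugs:
                return None, REASON_MISSING_CONCOMITANT
            return pattern, None
    return None, REASON_UNRECOGNIZED_ANCHOR


def merge_supply_days(starts, supplies) -> tuple[int, int]:
    """Era merge on integer day numbers: returns (merged supply end, number of
    prescriptions used).  ``starts`` must be sorted ascending; a prescription
    covers ``[start, start + supply - 1]`` and a successor starting more than
    the 28-day gap after the running supply end opens a new era (ignored:
    only the first era is analysed)."""
    supply_end = int(starts[0]) + int(supplies[0]) - 1
    n_used = 1
    for start, supply in zip(starts[1:], supplies[1:]):
        if int(start) - supply_end > ERA_GAP_DAYS:
            break
        end = int(start) + int(supply) - 1
        if end > supply_end:
            supply_end = end
        n_used += 1
    return supply_end, n_used


def classify_pattern(
    entry, prescriptions: pd.DataFrame
) -> tuple[Optional[ExposurePattern], Optional[str]]:
    """Assign a prescription pattern, or explain why none applies.

    ``entry`` must carry ``patient_id``, ``t0`` and ``daa_drugs_at_t0`` and
    have passed the multiple-DAA exclusion check.  Returns
    ``(pattern, None)`` on success or ``(None, reason)`` where ``reason`` is
    :data:`REASON_MISSING_CONCOMITANT` (required combination drugs absent
    from the +-30-day window, feeding exclusion criterion 6) or
    :data:`REASON_UNRECOGNIZED_ANCHOR`.
    """
    rx = prescriptions
    if "patient_id" in rx.columns and rx["patient_id"].nunique() > 1:
        rx = rx[rx["patient_id"] == entry.patient_id]
    anchor = frozenset(entry.daa_drugs_at_t0)
    if not anchor:
        raise ClassificationError(f"patient {entry.patient_id!r}: empty DAA set at t0")
    return classify_drug_sets(anchor, _window_drugs(rx, entry.t0))


def build_treatment_episode(
    entry,
    pattern: ExposurePattern,
    prescriptions: pd.DataFrame,
    study_end: pd.Timestamp,
) -> TreatmentEpisode:
    """Merge the pattern's era-defining prescriptions into one episode.

    A prescription covers ``[start, start + days_supply - 1]``.  A later
    prescription starting no more than 28 days after the current merged
    supply end extends the era; the first longer gap ends it (only the first
    era from t0 is analysed).  The final supply end gains 7 grace days,
    truncated at study end.
    """
    rx = prescriptions
    if "patient_id" in rx.columns and rx["patient_id"].nunique() > 1:
        rx = rx[rx["patient_id"] == entry.patient_id]
    t0 = entry.t0
    rx = rx[rx["drug"].isin(pattern.episode_drugs) & (rx["start_date"] >= t0)]
    rx = rx.sort_values("start_date")
    if rx.empty or (rx["start_date"].iloc[0] - t0).days > CONCOMITANCY_WINDOW_DAYS:
        raise ClassificationError(
            f"patient {entry.patient_id!r}: no {sorted(pattern.episode_drugs)} "
            "prescription at or shortly after t0")
    start_days = rx["start_date"].to_numpy("datetime64[D]").astype("int64")
    supply_end_day, n_used = merge_supply_days(
        start_days, rx["days_supply"].to_numpy("int64"))
    supply_end = pd.Timestamp(supply_end_day, unit="D")
    raw_end = supply_end + pd.Timedelta(days=ERA_GRACE_DAYS)
    truncated = raw_end > study_end
    return TreatmentEpisode(
        patient_id=entry.patient_id, pattern=pattern, start=t0,
        supply_end=supply_end, end=min(raw_end, study_end),
        truncated=truncated, n_prescriptions=n_used)


def detect_pattern_change(
    entry,
    pattern: ExposurePattern,
    prescriptions: pd.DataFrame,
    episode: TreatmentEpisode,
) -> Optional[pd.Timestamp]:
    """First date after t0, within the episode, with a foreign-pattern DAA
    prescription; ``None`` if exposure stays within the assigned pattern."""
    rx = prescriptions
    if "patient_id" in rx.columns and rx["patient_id"].nunique() > 1:
        rx = rx[rx["patient_id"] == entry.patient_id]
    foreign = TARGET_DAAS - pattern.anchor
    mask = (rx["drug"].isin(foreign)
            & (rx["start_date"] > entry.t0)
            & (rx["start_date"] <= episode.end))
    if not mask.any():
        return None
    return rx.loc[mask, "start_date"].min()
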