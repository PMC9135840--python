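"""Kidney-function outcome derivation.

From dated laboratory results this module derives one eGFR value per
patient-day (recorded eGFR taking precedence over serum-creatinine
conversion, same-day values averaged), maps values onto the ordered KDIGO
G categories, fixes the pre-index baseline, and scans the follow-up window
for the category-drop outcome with the full censoring logic: follow-up runs
from the index date t0 to the first of outcome, treatment end, prescription
pattern change, or study end.

eGFR is estimated from serum creatinine with the Japanese GFR equation:

    male:   eGFR = 194 * sCRE**-1.094 * age**-0.287
    female: eGFR = male value * 0.739

with sCRE in mg/dL, age in completed years at the measurement date, eGFR in
mL/min/1.73 m^2.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

import numpy as np
import pandas as pd


class KidneyCategory(enum.IntEnum):
    """Ordered KDIGO G categories; lower index = better kidney function.

    Lower bounds are inclusive: eGFR exactly 90 is NORMAL, exactly 60 MILD,
    and so on; eGFR below 15 is FAILURE.
    """

    NORMAL = 0           # eGFR >= 90
    MILD = 1             # 90 > eGFR >= 60
    MILD_MODERATE = 2    # 60 > eGFR >= 45
    MODERATE_SEVERE = 3  # 45 > eGFR >= 30
    SEVERE = 4           # 30 > eGFR >= 15
    FAILURE = 5          # 15 > eGFR


#: Category boundaries, ascending; used by the vectorised categoriser.
CATEGORY_BOUNDS = np.array([15.0, 30.0, 45.0, 60.0, 90.0])

#: Inclusive lower bound of each category (FAILURE has no positive lower bound).
CATEGORY_LOWER_BOUND = {
    KidneyCategory.NORMAL: 90.0,
    KidneyCategory.MILD: 60.0,
    KidneyCategory.MILD_MODERATE: 45.0,
    KidneyCategory.MODERATE_SEVERE: 30.0,
    KidneyCategory.SEVERE: 15.0,
    KidneyCategory.FAILURE: 0.0,
}


def categorize(egfr: float) -> KidneyCategory:
    """Map an eGFR value (mL/min/1.73 m^2) to its KDIGO G category."""
    if not egfr > 0:
        raise ValueError(f"eGFR must be positive, got {egfr!r}")
    return KidneyCategory(5 - int(np.searchsorted(CATEGORY_BOUNDS, egfr, side="right")))


def categorize_values(values: np.ndarray) -> np.ndarray:
    """Vectorised :func:`categorize`; returns integer category indices."""
    values = np.asarray(values, dtype=float)
    if values.size and not (values > 0).all():
        raise ValueError("eGFR values must be positive")
    return 5 - np.searchsorted(CATEGORY_BOUNDS, values, side="right")


def egfr_from_scre(scre: float, age: float, sex: str) -> float:
    """Estimated GFR from serum creatinine (Japanese GFR equation).

    Parameters
    ----------
    scre : serum creatinine, mg/dL (> 0)
    age : age in years (> 0)
    sex : ``"male"`` or ``"female"``; the female estimate is the male
        estimate multiplied by 0.739.
    """
    if not scre > 0:
        raise ValueError(f"sCRE must be positive, got {scre!r}")
    if not age > 0:
        raise ValueError(f"age must be positive, got {age!r}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    value = 194.0 * scre ** -1.094 * age ** -0.287
    if sex == "female":
        value *= 0.739
    return value


def _egfr_from_scre_vec(scre: np.ndarray, age: np.ndarray, female: np.ndarray) -> np.ndarray:
    value = 194.0 * scre ** -1.094 * age ** -0.287
    return np.where(female, value * 0.739, value)


def completed_years(dates: pd.Series, birth_dates: pd.Series) -> np.ndarray:
    """Age in completed (whole) years at each date, vectorised."""
    d_year, d_month, d_day = dates.dt.year.values, dates.dt.month.values, dates.dt.day.values
    b_year, b_month, b_day = (birth_dates.dt.year.values, birth_dates.dt.month.values,
                              birth_dates.dt.day.values)
    not_yet = (d_month < b_month) | ((d_month == b_month) & (d_day < b_day))
    return d_year - b_year - not_yet.astype(int)


def build_daily_egfr(labs: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """One eGFR value per patient-day.

    Recorded eGFR values take precedence; a day with only serum creatinine
    uses the converted value.  Multiple same-source values on one day are
    averaged.  Age for the conversion is the patient's completed years at
    the laboratory date.

    Returns a frame with columns ``patient_id``, ``date``, ``value``,
    ``source`` (``recorded`` / ``converted_from_sCRE`` / ``mean_of_multiple``).
    """
    columns = ["patient_id", "date", "value", "source"]
    if labs.empty:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(columns, [object, "datetime64[ns]", float, object])})
    egfr = labs[labs["analyte"] == "eGFR"]
    recorded = (
        egfr.groupby(["patient_id", "date"])["value"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "value", "size": "n"})
    )
    recorded["source"] = np.where(recorded["n"] > 1, "mean_of_multiple", "recorded")

    scre = labs[labs["analyte"] == "sCRE"]
    if len(scre):
        scre = scre.merge(patients[["patient_id", "sex", "birth_date"]],
                          on="patient_id", how="left", validate="many_to_one")
        if scre["sex"].isna().any():
            missing = scre.loc[scre["sex"].isna(), "patient_id"].iloc[0]
            raise ValueError(f"lab result for unknown patient {missing!r}")
        age = completed_years(scre["date"], scre["birth_date"])
        converted_values = _egfr_from_scre_vec(
            scre["value"].to_numpy(float), age.astype(float),
            (scre["sex"] == "female").to_numpy())
        converted = (
            scre.assign(value=converted_values)
            .groupby(["patient_id", "date"])["value"]
            .mean()
            .reset_index()
        )
        converted["source"] = "converted_from_sCRE"
        # keep converted values only on days without any recorded eGFR
        converted = converted.merge(
            recorded[["patient_id", "date"]], on=["patient_id", "date"],
            how="left", indicator=True)
        converted = converted[converted["_merge"] == "left_only"].drop(columns="_merge")
        out = pd.concat([recorded[columns], converted[columns]], ignore_index=True)
    else:
        out = recorded[columns].copy()
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def baseline_egfr(entry, daily_egfr: pd.DataFrame) -> tuple[float, KidneyCategory]:
    """Baseline value and category: the eGFR closest to t0 within the 90 days
    before t0 (window [t0-90, t0-1]; the t0-day value is never used)."""
    frame = daily_egfr
    if "patient_id" in frame.columns:
        frame = frame[frame["patient_id"] == entry.patient_id]
    t0 = entry.t0
    window = frame[(frame["date"] >= t0 - pd.Timedelta(days=90))
                   & (frame["date"] <= t0 - pd.Timedelta(days=1))]
    if window.empty:
        raise ValueError(
            f"patient {entry.patient_id!r}: no kidney-function value in the 90 days "
            "before t0 (should have been excluded upstream)")
    value = float(window.loc[window["date"].idxmax(), "value"])
    return value, categorize(value)


@dataclasses.dataclass
class FollowUpResult:
    """Per-patient follow-up outcome.

    ``person_days`` is the integer day count from t0 to ``end_date``; it is 0
    when every candidate end date coincides with t0.
    """

    patient_id: str
    pattern: object
    baseline_egfr: float
    baseline_category: KidneyCategory
    outcome: str           # "event" | "censored"
    end_date: pd.Timestamp
    end_reason: str        # "outcome" | "treatment_end" | "pattern_change" | "study_end"
    person_days: int


def follow_up(
    entry,
    pattern,
    episode,
    daily_egfr: pd.DataFrame,
    change_date: Optional[pd.Timestamp],
    study_end: pd.Timestamp,
    drop_threshold: int = 1,
) -> FollowUpResult:
    """Detect the category-drop outcome and the censoring end point.

    Patient-days strictly after t0 and at or before the censoring horizon are
    scanned in date order; the first day whose category index is at least
    ``drop_threshold`` above the baseline category is the event day.  The
    horizon is the first of: treatment-episode end, the day before a pattern
    change, and study end.  A same-day tie between the outcome and a
    censoring date records the event (the outcome is listed first in the
    study design's end-point rule).
    """
    if drop_threshold not in (1, 2):
        raise ValueError("drop_threshold must be 1 or 2")
    base_value, base_cat = baseline_egfr(entry, daily_egfr)
    t0 = entry.t0

    candidates: list[tuple[pd.Timestamp, str]] = []
    if episode.truncated and episode.end == study_end:
        candidates.append((episode.end, "study_end"))
    else:
        candidates.append((episode.end, "treatment_end"))
    if change_date is not None:
        candidates.append((change_date - pd.Timedelta(days=1), "pattern_change"))
    candidates.append((study_end, "study_end"))
    horizon = min(date for date, _ in candidates)
    # tie-break in the design's stated order: treatment end, pattern change, study end
    order = {"treatment_end": 0, "pattern_change": 1, "study_end": 2}
    reason = min((r for d, r in candidates if d == horizon), key=order.__getitem__)

    frame = daily_egfr
    if "patient_id" in frame.columns:
        frame = frame[frame["patient_id"] == entry.patient_id]
    scan = frame[(frame["date"] > t0) & (frame["date"] <= horizon)].sort_values("date")
    if len(scan):
        cats = categorize_values(scan["value"].to_numpy())
        hits = np.nonzero(cats >= int(base_cat) + drop_threshold)[0]
        if hits.size:
            event_date = scan["date"].iloc[int(hits[0])]
            return FollowUpResult(
                patient_id=entry.patient_id, pattern=pattern,
                baseline_egfr=base_value, baseline_category=base_cat,
                outcome="event", end_date=event_date, end_reason="outcome",
                person_days=int((event_date - t0).days))
    end_date = max(horizon, t0)  # horizon before t0 collapses to zero follow-up
    return FollowUpResult(
        patient_id=entry.patient_id, pattern=pattern,
        baseline_egfr=base_value, baseline_category=base_cat,
        outcome="censored", end_date=end_date, end_reason=reason,
        person_days=int((end_date - t0).days))
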