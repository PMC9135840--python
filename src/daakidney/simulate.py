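"""Synthetic EHR generator with injected ground truth.

Emulates the structure the pipeline assumes: dated prescription records with
days of supply, dated kidney-function laboratory results at realistic test
frequency, diagnosis/procedure records carrying the exclusion criteria, and
per-pattern hazards of kidney-function decline.

The event mechanism is a latent exponential event time per patient, with
rate ``event_rate_control * rate_ratio_per_pattern[pattern]`` per
person-year.  An event is only observable on a laboratory-test day: on the
first test day at or after the latent time the generated eGFR falls strictly
below the lower bound of the patient's baseline category (one category down,
occasionally two); on other days values fluctuate inside the baseline
category, so the ground truth is unambiguous.  This reproduces the
interval-censored detection inherent to outcomes read off measurement
times.

A single global seed drives a hierarchical per-patient substream
(:class:`numpy.random.SeedSequence` spawning), so enlarging ``n_patients``
leaves earlier patients' records byte-identical.
"""

from __future__ import annotations

import dataclasses
import math
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .ehr import TABLE_SCHEMAS, StudyDataset, empty_tables
from .exposure import ExposurePattern
from .outcome import KidneyCategory, categorize

_EPOCH = date(1970, 1, 1)


def _age_completed_years(day_number: int, birth_day_number: int) -> int:
    d = _EPOCH + timedelta(days=int(day_number))
    b = _EPOCH + timedelta(days=int(birth_day_number))
    return d.year - b.year - ((d.month, d.day) < (b.month, b.day))

PATTERN_CODES = tuple(p.value for p in ExposurePattern)
NON_USER = "non_user"

#: Exclusion-criterion carrier labels used in the config and ground truth.
EXCLUSION_KEYS = (
    "diabetes", "heart_failure", "hypertension",
    "renal_disease", "dialysis_transplant", "missing_baseline_lab",
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_pattern_probabilities() -> dict[str, float]:
    # mixture roughly proportional to the per-pattern cohort shares reported
    # for the source database, with a non-user background fraction
    return {
        "P1": 0.080, "P2": 0.085, "P3": 0.208, "P4": 0.007, "P5": 0.162,
        "P6": 0.016, "P7": 0.247, "P8": 0.038, "P9": 0.007, "P10": 0.0,
        NON_USER: 0.15,
    }


def _default_rate_ratios() -> dict[str, float]:
    return {code: 1.0 for code in PATTERN_CODES}


def _default_exclusion_prevalences() -> dict[str, float]:
    # comorbidity prevalences chosen so the union of exclusions removes a
    # majority of new users, echoing the attrition scale of the source cohort
    return {
        "diabetes": 0.20, "heart_failure": 0.08, "hypertension": 0.35,
        "renal_disease": 0.05, "dialysis_transplant": 0.01,
        "missing_baseline_lab": 0.15,
    }


def _default_treatment_durations() -> dict[str, int]:
    # intended regimen lengths, days: 24 weeks for DCV+ASV, 12 weeks otherwise
    return {code: (168 if code == "P3" else 84) for code in PATTERN_CODES}


@dataclasses.dataclass
class SimulationConfig:
    """Generator parameters; defaults describe the emulated study population.

    ``pattern_probabilities`` is a simplex over the ten patterns plus
    ``"non_user"``; ``age_distribution`` and ``baseline_egfr_distribution``
    are (location, scale) of truncated normals (years; mL/min/1.73 m^2);
    ``lab_interval_days`` is the mean gap between kidney-function tests;
    ``event_rate_control`` is the decline hazard in the control pattern per
    person-year and ``rate_ratio_per_pattern`` the true multiplicative IRR
    per pattern (control must be 1).
    """

    n_patients: int = 1000
    seed: int = 0
    pattern_probabilities: dict[str, float] = dataclasses.field(
        default_factory=_default_pattern_probabilities)
    age_distribution: tuple[float, float] = (65.0, 12.0)
    female_fraction: float = 0.57
    baseline_egfr_distribution: tuple[float, float] = (75.0, 13.0)
    lab_interval_days: float = 20.0
    event_rate_control: float = 0.5
    rate_ratio_per_pattern: dict[str, float] = dataclasses.field(
        default_factory=_default_rate_ratios)
    exclusion_prevalences: dict[str, float] = dataclasses.field(
        default_factory=_default_exclusion_prevalences)
    history_days_distribution: tuple[float, float] = (400.0, 250.0)
    treatment_duration_days: dict[str, int] = dataclasses.field(
        default_factory=_default_treatment_durations)
    study_start: str = "2009-01-01"
    study_end: str = "2017-12-31"

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        probs = self.pattern_probabilities
        unknown = set(probs) - set(PATTERN_CODES) - {NON_USER}
        if unknown:
            raise ConfigError(f"unknown pattern keys {sorted(unknown)}")
        if any(p < 0 or p > 1 for p in probs.values()):
            raise ConfigError("pattern probabilities must lie in [0, 1]")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"pattern probabilities sum to {total}, expected 1")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigError("female_fraction must lie in [0, 1]")
        if self.event_rate_control < 0:
            raise ConfigError("event_rate_control must be >= 0")
        if any(r < 0 for r in self.rate_ratio_per_pattern.values()):
            raise ConfigError("rate ratios must be >= 0")
        control = ExposurePattern.P7_LDV_SOF.value
        if self.rate_ratio_per_pattern.get(control, 1.0) != 1.0:
            raise ConfigError("the control pattern's rate ratio must be 1")
        for key, p in self.exclusion_prevalences.items():
            if key not in EXCLUSION_KEYS:
                raise ConfigError(f"unknown exclusion key {key!r}")
            if not 0 <= p <= 1:
                raise ConfigError(f"exclusion prevalence {key} outside [0, 1]")
        if self.lab_interval_days <= 0:
            raise ConfigError("lab_interval_days must be positive")
        return self

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["age_distribution"] = list(self.age_distribution)
        data["baseline_egfr_distribution"] = list(self.baseline_egfr_distribution)
        data["history_days_distribution"] = list(self.history_days_distribution)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("age_distribution", "baseline_egfr_distribution",
                    "history_days_distribution"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data).validate()


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                      low: float, high: float) -> float:
    for _ in range(1000):
        x = rng.normal(loc, scale)
        if low <= x <= high:
            return x
    return float(np.clip(loc, low, high))


_CATEGORY_UPPER = {  # exclusive upper bound per category (NORMAL open-ended)
    KidneyCategory.NORMAL: None, KidneyCategory.MILD: 90.0,
    KidneyCategory.MILD_MODERATE: 60.0, KidneyCategory.MODERATE_SEVERE: 45.0,
    KidneyCategory.SEVERE: 30.0, KidneyCategory.FAILURE: 15.0,
}
_CATEGORY_LOWER = {
    KidneyCategory.NORMAL: 90.0, KidneyCategory.MILD: 60.0,
    KidneyCategory.MILD_MODERATE: 45.0, KidneyCategory.MODERATE_SEVERE: 30.0,
    KidneyCategory.SEVERE: 15.0, KidneyCategory.FAILURE: 5.0,
}


def _value_in_category(rng: np.random.Generator, category: KidneyCategory,
                       anchor: float) -> float:
    """A value inside the category, fluctuating near ``anchor`` but never
    crossing a boundary (0.2 margin keeps float categorisation unambiguous)."""
    lo = _CATEGORY_LOWER[category] + 0.2
    hi = _CATEGORY_UPPER[category]
    hi = max(anchor + 15.0, lo + 10.0) if hi is None else hi - 0.2
    lo2, hi2 = max(lo, anchor - 8.0), min(hi, anchor + 8.0)
    if lo2 >= hi2:
        lo2, hi2 = lo, hi
    return float(rng.uniform(lo2, hi2))


def _scre_for_egfr(egfr: float, age: float, female: bool) -> float:
    """Invert the Japanese GFR equation: the sCRE reproducing this eGFR."""
    base = 194.0 * age ** -0.287 * (0.739 if female else 1.0)
    return (egfr / base) ** (-1.0 / 1.094)


#: Anchor/concomitant drugs dispensed per pattern: (era drug refilled over the
#: regimen, other drugs dispensed once on t0).
_PATTERN_DISPENSE: dict[str, tuple[str, tuple[str, ...]]] = {
    "P1": ("TVR", ("PEG_IFN", "RIB")),
    "P2": ("SMV", ("PEG_IFN", "RIB")),
    "P3": ("DCV", ("ASV",)),
    "P4": ("VAN", ("PEG_IFN", "RIB")),
    "P5": ("SOF", ("RIB",)),
    "P6": ("EBV", ("GZR",)),
    "P7": ("LDV_SOF", ()),
    "P8": ("OBV_PTV_r", ()),
    "P9": ("OBV_PTV_r", ("RIB",)),
    "P10": ("DCV_ASV_BCV", ()),
}


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[StudyDataset, pd.DataFrame]:
    """Generate a study dataset and its ground-truth table.

    Deterministic given ``config.seed``.  The ground truth records, per
    patient: the assigned pattern (or ``non_user``), the true baseline eGFR,
    the latent event day (days from t0; NaN when no event was drawn), the
    index date, and one carrier flag per exclusion criterion plus the
    insufficient-history flag.
    """
    config.validate()
    study_start = pd.Timestamp(config.study_start)
    study_end = pd.Timestamp(config.study_end)
    start_day = study_start.value // 86_400_000_000_000  # days since epoch
    end_day = study_end.value // 86_400_000_000_000

    labels = list(config.pattern_probabilities)
    probs = np.array([config.pattern_probabilities[k] for k in labels])
    cum = np.cumsum(probs) / probs.sum()

    patients_rows: list[tuple] = []
    rx_rows: list[tuple] = []
    lab_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    proc_rows: list[tuple] = []
    truth_rows: list[dict] = []

    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    prev = config.exclusion_prevalences
    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"S{i:06d}"
        pattern = labels[int(np.searchsorted(cum, rng.random(), side="right"))]
        female = rng.random() < config.female_fraction
        sex = "female" if female else "male"
        age = _truncated_normal(rng, *config.age_distribution, 20.0, 95.0)
        baseline = _truncated_normal(rng, *config.baseline_egfr_distribution,
                                     46.0, 130.0)
        base_cat = categorize(baseline)
        history = int(max(10.0, min(2500.0, rng.normal(
            *config.history_days_distribution))))
        if rng.random() < 0.10:
            # shortened history: every record of this patient stays inside it
            history = int(rng.integers(10, 90))
        # the drawn history itself may fall short of the 90-day new-user rule
        insufficient = history < 90

        carriers = {key: bool(rng.random() < prev.get(key, 0.0))
                    for key in EXCLUSION_KEYS}

        if pattern == NON_USER:
            # background patient: a little history, no target DAAs
            anchor_day = int(start_day + 200 + rng.random() * (end_day - start_day - 400))
            birth_day = anchor_day - int(age * 365.25) - 1
            patients_rows.append((pid, sex, birth_day))
            for _ in range(rng.integers(1, 4)):
                day = anchor_day + int(rng.integers(-180, 181))
                lab_rows.append((pid, day, "eGFR",
                                 round(_value_in_category(rng, base_cat, baseline), 1)))
            if rng.random() < 0.3:
                rx_rows.append((pid, "OTHER", anchor_day, int(rng.integers(7, 60))))
            truth_rows.append({
                "patient_id": pid, "pattern": NON_USER, "t0": pd.NaT,
                "true_baseline_egfr": baseline, "true_event_day": math.nan,
                "insufficient_history": False,
                **{f"carrier_{k}": carriers[k] for k in EXCLUSION_KEYS}})
            continue

        t0_lo = start_day + history
        t0_hi = end_day - 150
        if t0_lo > t0_hi:
            history = t0_hi - start_day
            t0_lo = t0_hi
        t0_day = int(t0_lo + rng.random() * (t0_hi - t0_lo + 1))
        birth_day = t0_day - int(age * 365.25) - 1
        patients_rows.append((pid, sex, birth_day))

        first_record = t0_day - history
        dx_rows.append((pid, first_record, "OTHER"))

        if carriers["diabetes"]:
            dx_rows.append((pid, t0_day - int(rng.integers(1, history + 1)), "diabetes"))
        if carriers["heart_failure"]:
            dx_rows.append((pid, t0_day - int(rng.integers(1, history + 1)),
                            "heart_failure"))
        if carriers["hypertension"]:
            dx_rows.append((pid, t0_day - int(rng.integers(1, history + 1)),
                            "hypertension"))
        if carriers["renal_disease"]:
            cond = "chronic_kidney_disease" if rng.random() < 0.5 else "renal_failure"
            dx_rows.append((pid, t0_day - int(rng.integers(1, history + 1)), cond))
        if carriers["dialysis_transplant"]:
            proc = ("renal_dialysis" if rng.random() < 0.8 else "renal_transplantation")
            proc_rows.append((pid, t0_day - int(rng.integers(1, history + 1)), proc))

        def record_lab(day: int, value: float) -> None:
            # a fraction of kidney-function results arrive as serum creatinine
            if rng.random() < 0.2:
                age_at = _age_completed_years(day, birth_day)
                scre = _scre_for_egfr(value, float(age_at), female)
                lab_rows.append((pid, day, "sCRE", round(scre, 3)))
            else:
                lab_rows.append((pid, day, "eGFR", round(value, 1)))
                if rng.random() < 0.05:  # same-day duplicate exercises averaging
                    lab_rows.append((pid, day, "eGFR",
                                     round(_value_in_category(
                                         rng, categorize(value), value), 1)))

        if not carriers["missing_baseline_lab"]:
            n_base = int(rng.integers(2, 5))
            off_hi = min(86, history)  # pre-index labs never predate the history
            days = sorted(set(t0_day - int(d)
                              for d in rng.integers(3, off_hi, size=n_base)))
            for day in days:
                record_lab(day, _value_in_category(rng, base_cat, baseline))

        # prescriptions: era drug refilled in 28-day supplies over the regimen
        era_drug, concomitants = _PATTERN_DISPENSE[pattern]
        duration = int(config.treatment_duration_days.get(pattern, 84))
        day = t0_day
        dispensed = 0
        last_supply_end = t0_day
        while dispensed < duration:
            supply = int(min(28, duration - dispensed))
            rx_rows.append((pid, era_drug, day, supply))
            last_supply_end = day + supply - 1
            dispensed += supply
            day = last_supply_end + 1 + int(rng.integers(0, 8))
        for drug in concomitants:
            rx_rows.append((pid, drug, t0_day, min(84, duration)))

        rr = config.rate_ratio_per_pattern.get(pattern, 1.0)
        rate = config.event_rate_control * rr
        event_day = rng.exponential(365.25 / rate) if rate > 0 else math.nan

        # post-index labs on a stochastic grid until shortly past the era end
        day = t0_day
        horizon = last_supply_end + 40
        mean_gap = config.lab_interval_days
        event_cat: Optional[KidneyCategory] = None
        while True:
            day += int(rng.integers(max(2, int(mean_gap) - 10),
                                    int(mean_gap) + 11))
            if day > min(horizon, end_day):
                break
            offset = day - t0_day
            if event_cat is None and not math.isnan(event_day) and offset >= event_day:
                depth = 2 if rng.random() < 0.25 else 1
                event_cat = KidneyCategory(min(5, int(base_cat) + depth))
            if event_cat is not None:
                value = _value_in_category(rng, event_cat,
                                           _CATEGORY_LOWER[event_cat] + 5.0)
            else:
                value = _value_in_category(rng, base_cat, baseline)
            record_lab(day, value)

        truth_rows.append({
            "patient_id": pid, "pattern": pattern,
            "t0": pd.Timestamp(t0_day, unit="D"),
            "true_baseline_egfr": baseline,
            "true_event_day": event_day,
            "insufficient_history": insufficient,
            **{f"carrier_{k}": carriers[k] for k in EXCLUSION_KEYS}})

    tables = empty_tables()
    if patients_rows:
        def days_to_ts(col: pd.Series) -> pd.Series:
            return pd.to_datetime(col, unit="D")

        tables["patients"] = pd.DataFrame(
            patients_rows, columns=list(TABLE_SCHEMAS["patients"]))
        tables["patients"]["birth_date"] = days_to_ts(tables["patients"]["birth_date"])
        if rx_rows:
            tables["prescriptions"] = pd.DataFrame(
                rx_rows, columns=list(TABLE_SCHEMAS["prescriptions"]))
            tables["prescriptions"]["start_date"] = days_to_ts(
                tables["prescriptions"]["start_date"])
        if lab_rows:
            tables["labs"] = pd.DataFrame(lab_rows, columns=list(TABLE_SCHEMAS["labs"]))
            tables["labs"]["date"] = days_to_ts(tables["labs"]["date"])
        if dx_rows:
            tables["diagnoses"] = pd.DataFrame(
                dx_rows, columns=list(TABLE_SCHEMAS["diagnoses"]))
            tables["diagnoses"]["date"] = days_to_ts(tables["diagnoses"]["date"])
        if proc_rows:
            tables["procedures"] = pd.DataFrame(
                proc_rows, columns=list(TABLE_SCHEMAS["procedures"]))
            tables["procedures"]["date"] = days_to_ts(tables["procedures"]["date"])

    dataset = StudyDataset(study_start=study_start, study_end=study_end, **tables)
    truth = pd.DataFrame(truth_rows) if truth_rows else pd.DataFrame(
        columns=["patient_id", "pattern", "t0", "true_baseline_egfr",
                 "true_event_day", "insufficient_history",
                 *[f"carrier_{k}" for k in EXCLUSION_KEYS]])
    return dataset, truth


def null_config(n_patients: int = 500, seed: int = 0) -> SimulationConfig:
    """All true rate ratios 1: the null configuration for type-I-error runs."""
    return SimulationConfig(n_patients=n_patients, seed=seed)


def recovery_config(
    true_irr: float = 5.0,
    pattern: str = "P5",
    n_patients: int = 2000,
    seed: int = 0,
) -> SimulationConfig:
    """Two-arm configuration for parameter-recovery runs: one pattern with an
    injected rate ratio against the control, other patterns absent."""
    probs = {code: 0.0 for code in PATTERN_CODES}
    probs[pattern] = 0.40
    probs["P7"] = 0.45
    probs[NON_USER] = 0.15
    ratios = _default_rate_ratios()
    ratios[pattern] = true_irr
    return SimulationConfig(
        n_patients=n_patients, seed=seed,
        pattern_probabilities=probs, rate_ratio_per_pattern=ratios)
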