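"""Hand-constructed miniature datasets with exhaustively known pipeline
outputs, for tests and worked examples.

Three fixtures are provided:

``tiny``
    A dozen patients covering every prescription pattern, each passing the
    eligibility criteria, with a few constructed outcome events.
``attrition``
    One patient per selection-flowchart step (the insufficient-history rule
    and each of the six exclusion criteria), one patient carrying two
    criteria at once (exercising duplicate counting), and two eligible
    patients.
``null``
    A simulated dataset in which every true rate ratio is 1.

The ground-truth table of the hand-built fixtures carries one boolean column
per attrition step plus the expected pattern and event day for eligible
patients, so tests can compare pipeline output against construction.
"""

from __future__ import annotations

import pandas as pd

from .ehr import TABLE_SCHEMAS, StudyDataset, empty_tables
from .simulate import null_config, simulate_dataset

STUDY_WINDOW = ("2009-01-01", "2017-12-31")
_T0 = pd.Timestamp("2015-06-01")


def _build(patients, prescriptions, labs, diagnoses, procedures) -> StudyDataset:
    tables = empty_tables()
    raw = {"patients": patients, "prescriptions": prescriptions, "labs": labs,
           "diagnoses": diagnoses, "procedures": procedures}
    date_cols = {"patients": "birth_date", "prescriptions": "start_date",
                 "labs": "date", "diagnoses": "date", "procedures": "date"}
    for name, rows in raw.items():
        if not rows:
            continue
        frame = pd.DataFrame(rows, columns=list(TABLE_SCHEMAS[name]))
        frame[date_cols[name]] = pd.to_datetime(frame[date_cols[name]])
        tables[name] = frame
    return StudyDataset(study_start=pd.Timestamp(STUDY_WINDOW[0]),
                        study_end=pd.Timestamp(STUDY_WINDOW[1]), **tables)


def _day(offset: int) -> pd.Timestamp:
    return _T0 + pd.Timedelta(days=offset)


_BIRTH = "1955-01-01"  # age 60 at the common index date


def _tiny() -> tuple[StudyDataset, pd.DataFrame]:
    """Twelve patients, one per pattern plus extra controls.

    Every patient: history diagnosis at t0-200, baseline eGFR 75 recorded at
    t0-14 (category MILD, 60-89), era drug dispensed on t0 with a 28-day
    supply plus one contiguous refill (56 covered days, era end t0+62 after
    grace).  Constructed events: T01 (value 52 on day 21: one-category drop),
    T03 (value 40 on day 28: two-category drop), T09 (value 55 on day 35) and
    control patient T11 (value 58 on day 42).  T12 switches pattern (foreign
    DAA on day 30).
    """
    specs = [
        # pid, era drug, concomitants at t0, expected pattern
        ("T01", "TVR", ("PEG_IFN", "RIB"), "P1"),
        ("T02", "SMV", ("PEG_IFN", "RIB"), "P2"),
        ("T03", "DCV", ("ASV",), "P3"),
        ("T04", "VAN", ("PEG_IFN", "RIB"), "P4"),
        ("T05", "SOF", ("RIB",), "P5"),
        ("T06", "EBV", ("GZR",), "P6"),
        ("T07", "LDV_SOF", (), "P7"),
        ("T08", "OBV_PTV_r", (), "P8"),
        ("T09", "OBV_PTV_r", ("RIB",), "P9"),
        ("T10", "DCV_ASV_BCV", (), "P10"),
        ("T11", "LDV_SOF", (), "P7"),
        ("T12", "LDV_SOF", (), "P7"),
    ]
    events = {"T01": (21, 52.0), "T03": (28, 40.0), "T09": (35, 55.0),
              "T11": (42, 58.0)}
    patients, rx, labs, dx = [], [], [], []
    truth = []
    for pid, era_drug, concomitants, pattern in specs:
        sex = "female" if pid in ("T02", "T05", "T09", "T11") else "male"
        patients.append((pid, sex, _BIRTH))
        dx.append((pid, _day(-200), "OTHER"))
        labs.append((pid, _day(-14), "eGFR", 75.0))
        rx.append((pid, era_drug, _day(0), 28))
        rx.append((pid, era_drug, _day(28), 28))
        for drug in concomitants:
            rx.append((pid, drug, _day(0), 28))
        event_day = None
        if pid in events:
            day, value = events[pid]
            labs.append((pid, _day(day), "eGFR", value))
            event_day = day
        else:
            labs.append((pid, _day(21), "eGFR", 73.0))
        change_day = None
        if pid == "T12":
            rx.append((pid, "SOF", _day(30), 28))
            rx.append((pid, "RIB", _day(30), 28))
            change_day = 30
        truth.append({"patient_id": pid, "eligible": True,
                      "expected_pattern": pattern,
                      "expected_baseline": 75.0,
                      "expected_event_day": event_day,
                      "expected_change_day": change_day})
    dataset = _build(patients, rx, labs, dx, [])
    return dataset, pd.DataFrame(truth)


_ATTRITION_STEPS = ("insufficient_history", "low_baseline_egfr",
                    "renal_disease_history", "comorbidity",
                    "no_baseline_kidney_lab", "multiple_daas",
                    "missing_concomitant")


def _attrition() -> tuple[StudyDataset, pd.DataFrame]:
    patients, rx, labs, dx, proc = [], [], [], [], []
    truth = []

    def add(pid, steps=(), *, history_dx=True, baseline_lab=True,
            drugs=(("LDV_SOF", 0, 28),), pattern=None):
        patients.append((pid, "male", _BIRTH))
        if history_dx:
            dx.append((pid, _day(-200), "OTHER"))
        if baseline_lab:
            labs.append((pid, _day(-30), "eGFR", 75.0))
        for drug, offset, supply in drugs:
            rx.append((pid, drug, _day(offset), supply))
        row = {"patient_id": pid, "eligible": not steps,
               "expected_pattern": pattern}
        row.update({step: step in steps for step in _ATTRITION_STEPS})
        truth.append(row)

    add("A001", pattern="P7")
    # first record 89 days before t0: one day short of the history rule
    add("A002", ("insufficient_history",), history_dx=False)
    labs.append(("A002", _day(-89), "eGFR", 75.0))
    add("A003", ("low_baseline_egfr",))
    labs.append(("A003", _day(-10), "eGFR", 40.0))
    add("A004", ("renal_disease_history",))
    dx.append(("A004", _day(-150), "chronic_kidney_disease"))
    add("A005", ("comorbidity",))
    dx.append(("A005", _day(-1000), "hypertension"))
    add("A006", ("no_baseline_kidney_lab",), baseline_lab=False)
    labs.append(("A006", _day(-120), "eGFR", 75.0))  # outside the 90-day window
    add("A007", ("multiple_daas",),
        drugs=(("TVR", 0, 28), ("SMV", 0, 28), ("PEG_IFN", 0, 28), ("RIB", 0, 28)))
    add("A008", ("missing_concomitant",), drugs=(("TVR", 0, 28),))
    # two criteria at once: counted under each, removed once
    add("A009", ("renal_disease_history", "comorbidity"))
    dx.append(("A009", _day(-100), "renal_failure"))
    dx.append(("A009", _day(-50), "diabetes"))
    add("A010", drugs=(("DCV", 0, 28), ("ASV", 0, 28)), pattern="P3")
    labs.append(("A010", _day(21), "eGFR", 55.0))  # one-category drop on day 21

    dataset = _build(patients, rx, labs, dx, proc)
    return dataset, pd.DataFrame(truth)


def make_fixture(name: str, seed: int = 0) -> tuple[StudyDataset, pd.DataFrame]:
    """Return ``(dataset, ground_truth)`` for a named fixture.

    ``tiny`` and ``attrition`` are hand-constructed and ignore ``seed``;
    ``null`` simulates the all-rate-ratios-1 configuration with the given
    seed.
    """
    if name == "tiny":
        return _tiny()
    if name == "attrition":
        return _attrition()
    if name == "null":
        return simulate_dataset(null_config(seed=seed))
    raise ValueError(f"unknown fixture {name!r}; expected tiny, attrition or null")
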