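"""New-user identification and exclusion criteria (cohort attrition).

The index date t0 is a patient's first prescription date of any target DAA
inside the study window.  New users must have recorded history starting at
least 90 days before t0 (first recorded contact on any table at or before
t0 - 90).  Six exclusion criteria then restrict to patients with baseline
eGFR >= 45 mL/min/1.73 m^2 and without kidney-related risk factors:

  1. any eGFR below 45 within the 90 days before t0 (serum creatinine is
     converted where no recorded eGFR exists on the day);
  2. renal dialysis, renal transplantation, chronic kidney disease or renal
     failure recorded before t0;
  3. diabetes, heart failure or hypertension diagnosed before t0;
  4. no eGFR and no serum creatinine result within the 90 days before t0;
  5. multiple distinct target DAAs on t0, unless the combination is required
     by the package inserts (GZR+EBV or DCV+ASV);
  6. required concomitant drugs per the assigned pattern's package insert
     absent within 30 days before and after t0.

"Before t0" is strict (date < t0) and the 90-day lookback is the inclusive
window [t0-90, t0-1]; the t0-day value is never used.  A patient meeting
several criteria is counted once under each (duplicate counting, as in the
published attrition flowchart) while the final cohort removes the union.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import pandas as pd

from .ehr import TARGET_DAAS, StudyDataset
from .exposure import (PERMITTED_DAA_COMBINATIONS, ExposurePattern,
                       classify_pattern)
from .outcome import build_daily_egfr

#: Minimum recorded history before t0, days (inclusive: first record on
#: exactly t0-90 qualifies).
HISTORY_DAYS = 90
#: Baseline eGFR lookback window length, days.
BASELINE_WINDOW_DAYS = 90
#: Exclusion threshold for pre-index eGFR.
EGFR_EXCLUSION_THRESHOLD = 45.0

_RENAL_CONDITIONS = frozenset({"chronic_kidney_disease", "renal_failure"})
_RENAL_PROCEDURES = frozenset({"renal_dialysis", "renal_transplantation"})
_COMORBIDITIES = frozenset({"diabetes", "heart_failure", "hypertension"})

#: Attrition criteria in flowchart order (field name, human label).
CRITERIA = (
    ("low_baseline_egfr", "(1) eGFR < 45 within 90 days before t0"),
    ("renal_disease_history", "(2) dialysis/transplant/CKD/renal failure before t0"),
    ("comorbidity", "(3) diabetes/heart failure/hypertension before t0"),
    ("no_baseline_kidney_lab", "(4) no eGFR or sCRE within 90 days before t0"),
    ("multiple_daas", "(5) multiple DAAs at t0 not required by the PI"),
    ("missing_concomitant", "(6) required concomitant drugs absent (t0 +- 30 days)"),
)


@dataclasses.dataclass(frozen=True)
class CandidateEntry:
    """One potential new user: index date and the DAA set dispensed on it."""

    patient_id: str
    t0: pd.Timestamp
    daa_drugs_at_t0: frozenset[str]


@dataclasses.dataclass
class AttritionReport:
    """Counts mirroring the published selection flowchart.

    Per-criterion counts include duplicates (a patient meeting several
    criteria contributes to each); ``final_cohort_size`` removes the union.
    """

    new_users_identified: int = 0
    insufficient_history: int = 0
    low_baseline_egfr: int = 0
    renal_disease_history: int = 0
    comorbidity: int = 0
    no_baseline_kidney_lab: int = 0
    multiple_daas: int = 0
    missing_concomitant: int = 0
    final_cohort_size: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("new users identified", self.new_users_identified),
                ("excluded: history < 90 days before t0", self.insufficient_history)]
        rows += [(label, getattr(self, field)) for field, label in CRITERIA]
        rows.append(("final cohort", self.final_cohort_size))
        return pd.DataFrame(rows, columns=["step", "n"])

    def format_flowchart(self) -> str:
        lines = [f"new users of target DAAs            {self.new_users_identified:>7d}",
                 f"  - insufficient history (<90 d)    {self.insufficient_history:>7d}",
                 "  exclusion criteria (duplicate counting):"]
        for field, label in CRITERIA:
            lines.append(f"  - {label:<55s}{getattr(self, field):>5d}")
        lines.append(f"final analyzable cohort             {self.final_cohort_size:>7d}")
        return "\n".join(lines)


def find_new_users(dataset: StudyDataset) -> tuple[list[CandidateEntry], int]:
    """Identify new users of the target DAAs.

    Returns the candidates (one per patient, t0 = first target-DAA
    prescription date within the study window, with the DAA set dispensed on
    t0) and the count of patients dropped by the 90-day history requirement.
    """
    rx = dataset.prescriptions
    daa = rx[rx["drug"].isin(TARGET_DAAS)
             & (rx["start_date"] >= dataset.study_start)
             & (rx["start_date"] <= dataset.study_end)]
    if daa.empty:
        return [], 0
    t0 = daa.groupby("patient_id")["start_date"].min().rename("t0")
    at_t0 = daa.merge(t0, on="patient_id")
    at_t0 = at_t0[at_t0["start_date"] == at_t0["t0"]]
    drug_sets = at_t0.groupby("patient_id")["drug"].agg(frozenset)

    first = dataset.first_record_dates()
    frame = t0.to_frame().join(first, how="left").join(drug_sets.rename("daas"))
    enough_history = frame["first_record_date"] <= (
        frame["t0"] - pd.Timedelta(days=HISTORY_DAYS))
    n_insufficient = int((~enough_history).sum())
    kept = frame[enough_history]
    candidates = [
        CandidateEntry(patient_id=str(pid), t0=row.t0, daa_drugs_at_t0=row.daas)
        for pid, row in kept.iterrows()
    ]
    return candidates, n_insufficient


def _criterion_flags(
    candidates: list[CandidateEntry],
    dataset: StudyDataset,
    daily_egfr: Optional[pd.DataFrame],
    patterns: Optional[dict[str, Optional[ExposurePattern]]],
) -> pd.DataFrame:
    """Boolean flag per candidate per criterion (vectorised where it pays)."""
    idx = pd.Index([c.patient_id for c in candidates], name="patient_id")
    t0 = pd.Series([c.t0 for c in candidates], index=idx, name="t0")
    flags = pd.DataFrame(False, index=idx,
                         columns=[field for field, _ in CRITERIA])
    if not len(candidates):
        return flags

    if daily_egfr is None:
        labs = dataset.labs[dataset.labs["patient_id"].isin(idx)]
        daily_egfr = build_daily_egfr(labs, dataset.patients)
    daily = daily_egfr.merge(t0, on="patient_id")
    in_window = ((daily["date"] >= daily["t0"] - pd.Timedelta(days=BASELINE_WINDOW_DAYS))
                 & (daily["date"] <= daily["t0"] - pd.Timedelta(days=1)))
    window = daily[in_window]
    has_lab = window.groupby("patient_id").size()
    flags["no_baseline_kidney_lab"] = ~flags.index.isin(has_lab.index)
    low = window[window["value"] < EGFR_EXCLUSION_THRESHOLD]
    flags.loc[flags.index.isin(low["patient_id"]), "low_baseline_egfr"] = True

    dx = dataset.diagnoses.merge(t0, on="patient_id")
    dx = dx[dx["date"] < dx["t0"]]
    proc = dataset.procedures.merge(t0, on="patient_id")
    proc = proc[proc["date"] < proc["t0"]]
    renal_pids = set(dx.loc[dx["condition"].isin(_RENAL_CONDITIONS), "patient_id"])
    renal_pids |= set(proc.loc[proc["procedure"].isin(_RENAL_PROCEDURES), "patient_id"])
    flags.loc[flags.index.isin(renal_pids), "renal_disease_history"] = True
    comorbid = set(dx.loc[dx["condition"].isin(_COMORBIDITIES), "patient_id"])
    flags.loc[flags.index.isin(comorbid), "comorbidity"] = True

    rx_by_patient = dict(iter(
        dataset.prescriptions[dataset.prescriptions["patient_id"].isin(idx)]
        .groupby("patient_id")))
    for cand in candidates:
        multi = (len(cand.daa_drugs_at_t0) > 1
                 and cand.daa_drugs_at_t0 not in PERMITTED_DAA_COMBINATIONS)
        flags.loc[cand.patient_id, "multiple_daas"] = multi
        if multi:
            continue  # pattern rules are undefined for impermissible DAA sets
        if patterns is not None and cand.patient_id in patterns:
            pattern = patterns[cand.patient_id]
        else:
            pattern, _ = classify_pattern(cand, rx_by_patient[cand.patient_id])
        if pattern is None:
            flags.loc[cand.patient_id, "missing_concomitant"] = True
    return flags


def apply_exclusions(
    candidates: list[CandidateEntry],
    dataset: StudyDataset,
    daily_egfr: Optional[pd.DataFrame] = None,
    patterns: Optional[dict[str, Optional[ExposurePattern]]] = None,
    n_insufficient_history: int = 0,
) -> tuple[list[CandidateEntry], AttritionReport]:
    """Apply the six exclusion criteria and build the attrition report.

    ``daily_egfr`` (from :func:`~daakidney.outcome.build_daily_egfr`) and the
    pattern assignments may be passed in to avoid recomputation; both are
    derived from the dataset when omitted.
    """
    flags = _criterion_flags(candidates, dataset, daily_egfr, patterns)
    report = AttritionReport(
        new_users_identified=len(candidates) + n_insufficient_history,
        insufficient_history=n_insufficient_history,
        **{field: int(flags[field].sum()) for field, _ in CRITERIA},
    )
    excluded = flags.any(axis=1)
    cohort = [c for c in candidates if not excluded.get(c.patient_id, False)]
    report.final_cohort_size = len(cohort)
    return cohort, report
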