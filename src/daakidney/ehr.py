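"""Tabular electronic-health-record data model shared by all pipeline stages.

A study extract consists of five flat tables (patients, prescriptions,
laboratory results, diagnoses, procedures) plus the study window.  Tables are
held as :class:`pandas.DataFrame` with typed columns; dates are calendar dates
(``datetime64[ns]`` at midnight) and all date arithmetic is integer days —
times of day do not exist in this model.

The drug / condition / procedure vocabularies are deliberately small
abstractions: combination products (e.g. ledipasvir/sofosbuvir) are single
codes and are never decomposed, and anything outside the controlled
vocabulary is bucketed as ``OTHER`` at read time.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong layout."""


class ValidationError(ValueError):
    """A row violates a data-model invariant (bad date, non-positive value...)."""


#: Sexes as used by the Japanese GFR estimation equation.
SEXES = frozenset({"male", "female"})

#: Controlled drug vocabulary.  Combination products are single codes.
DRUG_CODES = (
    "TVR",          # telaprevir
    "SMV",          # simeprevir sodium
    "ASV",          # asunaprevir
    "DCV",          # daclatasvir hydrochloride
    "VAN",          # vaniprevir
    "SOF",          # sofosbuvir
    "GZR",          # grazoprevir hydrate
    "EBV",          # elbasvir
    "LDV_SOF",      # ledipasvir acetonate / sofosbuvir combination product
    "OBV_PTV_r",    # ombitasvir / paritaprevir / ritonavir combination product
    "DCV_ASV_BCV",  # daclatasvir / asunaprevir / beclabuvir combination product
    "PEG_IFN",      # peginterferon alpha
    "RIB",          # ribavirin
    "OTHER",
)

#: The direct-acting antivirals whose first prescription defines t0.
TARGET_DAAS = frozenset(
    {"TVR", "SMV", "ASV", "DCV", "VAN", "SOF", "GZR", "EBV",
     "LDV_SOF", "OBV_PTV_r", "DCV_ASV_BCV"}
)

CONDITIONS = (
    "diabetes",
    "heart_failure",
    "hypertension",
    "chronic_kidney_disease",
    "renal_failure",
    "OTHER",
)

PROCEDURES = ("renal_dialysis", "renal_transplantation", "OTHER")

ANALYTES = frozenset({"eGFR", "sCRE"})

TABLE_NAMES = ("patients", "prescriptions", "labs", "diagnoses", "procedures")

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "patients": ("patient_id", "sex", "birth_date"),
    "prescriptions": ("patient_id", "drug", "start_date", "days_supply"),
    "labs": ("patient_id", "date", "analyte", "value"),
    "diagnoses": ("patient_id", "date", "condition"),
    "procedures": ("patient_id", "date", "procedure"),
}

_DATE_COLUMNS: dict[str, tuple[str, ...]] = {
    "patients": ("birth_date",),
    "prescriptions": ("start_date",),
    "labs": ("date",),
    "diagnoses": ("date",),
    "procedures": ("date",),
}

_VOCAB_COLUMNS: dict[str, tuple[str, frozenset[str]]] = {
    # column, allowed values; unknown entries bucket to OTHER at read time
    "prescriptions": ("drug", frozenset(DRUG_CODES)),
    "diagnoses": ("condition", frozenset(CONDITIONS)),
    "procedures": ("procedure", frozenset(PROCEDURES)),
}


@dataclasses.dataclass
class StudyDataset:
    """The five study tables plus the study window.

    ``vocabulary_warnings`` counts rows whose drug/condition/procedure string
    was outside the controlled vocabulary and was bucketed as ``OTHER`` when
    the dataset was read from disk.
    """

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    study_start: pd.Timestamp
    study_end: pd.Timestamp
    vocabulary_warnings: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def first_record_dates(self) -> pd.Series:
        """Earliest dated record per patient across all four dated tables.

        The history requirement of the new-user rule is table-agnostic: any
        recorded contact (prescription, lab, diagnosis, procedure) counts.
        """
        pieces = [
            self.prescriptions[["patient_id", "start_date"]].rename(
                columns={"start_date": "date"}),
            self.labs[["patient_id", "date"]],
            self.diagnoses[["patient_id", "date"]],
            self.procedures[["patient_id", "date"]],
        ]
        dated = pd.concat(pieces, ignore_index=True)
        if dated.empty:
            return pd.Series(dtype="datetime64[ns]", name="first_record_date")
        out = dated.groupby("patient_id")["date"].min()
        out.name = "first_record_date"
        return out

    def copy(self) -> "StudyDataset":
        return StudyDataset(
            patients=self.patients.copy(),
            prescriptions=self.prescriptions.copy(),
            labs=self.labs.copy(),
            diagnoses=self.diagnoses.copy(),
            procedures=self.procedures.copy(),
            study_start=self.study_start,
            study_end=self.study_end,
            vocabulary_warnings=self.vocabulary_warnings,
        )

    def validate(self) -> "StudyDataset":
        """Enforce the data-model invariants; raise on the first violation."""
        for name in TABLE_NAMES:
            frame = self.table(name)
            missing = [c for c in TABLE_SCHEMAS[name] if c not in frame.columns]
            if missing:
                raise SchemaError(f"{name}: missing required column(s) {missing}")
        pats = self.patients
        if pats["patient_id"].duplicated().any():
            dupes = pats.loc[pats["patient_id"].duplicated(), "patient_id"]
            raise ValidationError(f"patients: duplicated patient_id {dupes.iloc[0]!r}")
        bad_sex = ~pats["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(
                f"patients: unknown sex at row {int(bad_sex.idxmax())}")
        if len(self.prescriptions):
            supply = self.prescriptions["days_supply"]
            if (supply < 1).any():
                raise ValidationError(
                    "prescriptions: days_supply must be >= 1 "
                    f"(row {int((supply < 1).idxmax())})")
        if len(self.labs):
            if not self.labs["analyte"].isin(ANALYTES).all():
                bad = ~self.labs["analyte"].isin(ANALYTES)
                raise ValidationError(f"labs: unknown analyte at row {int(bad.idxmax())}")
            value = self.labs["value"]
            bad_value = value.isna() | (value <= 0)
            if bad_value.any():
                raise ValidationError(
                    f"labs: value must be > 0 (row {int(bad_value.idxmax())})")
        for name, (col, allowed) in _VOCAB_COLUMNS.items():
            series = self.table(name)[col]
            if len(series) and not series.isin(allowed).all():
                bad = ~series.isin(allowed)
                raise ValidationError(
                    f"{name}: value {series[bad].iloc[0]!r} outside vocabulary "
                    f"(row {int(bad.idxmax())}); read_dataset buckets these as OTHER")
        # all dated records fall on or before study_end
        for name in TABLE_NAMES[1:]:
            for col in _DATE_COLUMNS[name]:
                dates = self.table(name)[col]
                if len(dates) and (dates > self.study_end).any():
                    raise ValidationError(f"{name}.{col}: record date after study_end")
        # birth precedes every dated record of the patient
        first = self.first_record_dates()
        if len(first):
            merged = pats.set_index("patient_id")["birth_date"].to_frame().join(first, how="inner")
            late = merged["birth_date"] > merged["first_record_date"]
            if late.any():
                raise ValidationError(
                    f"patient {merged.index[late][0]!r}: birth_date after first record")
        return self


def empty_tables() -> dict[str, pd.DataFrame]:
    """Header-only tables with the documented schemas and dtypes."""
    out: dict[str, pd.DataFrame] = {}
    for name, cols in TABLE_SCHEMAS.items():
        frame = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
        for col in _DATE_COLUMNS[name]:
            frame[col] = pd.Series(dtype="datetime64[ns]")
        if name == "prescriptions":
            frame["days_supply"] = pd.Series(dtype="int64")
        if name == "labs":
            frame["value"] = pd.Series(dtype="float64")
        out[name] = frame
    return out


def _parse_dates(frame: pd.DataFrame, table: str, col: str) -> pd.Series:
    parsed = pd.to_datetime(frame[col], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & frame[col].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValidationError(
            f"{table}: unparseable date {frame[col].iloc[row]!r} in column "
            f"{col!r} at row {row} (expected YYYY-MM-DD)")
    if parsed.isna().any():
        row = int(parsed.isna().idxmax())
        raise ValidationError(f"{table}: missing date in column {col!r} at row {row}")
    return parsed


def read_dataset(
    paths: Mapping[str, str | Path],
    study_window: tuple[str | pd.Timestamp, str | pd.Timestamp],
) -> StudyDataset:
    """Read and validate the five study tables.

    Parameters
    ----------
    paths
        Mapping with one CSV path per table name
        (``patients``, ``prescriptions``, ``labs``, ``diagnoses``, ``procedures``).
    study_window
        ``(study_start, study_end)`` calendar dates.

    Unknown drug/condition/procedure strings are mapped to ``OTHER``; the
    number of such rows is recorded on the returned dataset and reported via
    a single :class:`UserWarning`.  Structural problems raise
    :class:`SchemaError`; bad rows raise :class:`ValidationError` naming the
    row index.
    """
    missing_tables = [t for t in TABLE_NAMES if t not in paths]
    if missing_tables:
        raise SchemaError(f"no path given for table(s) {missing_tables}")
    tables: dict[str, pd.DataFrame] = {}
    n_bucketed = 0
    for name in TABLE_NAMES:
        path = Path(paths[name])
        if not path.exists():
            raise FileNotFoundError(path)
        frame = pd.read_csv(path, dtype={"patient_id": str})
        missing = [c for c in TABLE_SCHEMAS[name] if c not in frame.columns]
        if missing:
            raise SchemaError(f"{name} ({path}): missing required column(s) {missing}")
        frame = frame[list(TABLE_SCHEMAS[name])]
        for col in _DATE_COLUMNS[name]:
            frame[col] = _parse_dates(frame, name, col)
        if name in _VOCAB_COLUMNS:
            col, allowed = _VOCAB_COLUMNS[name]
            frame[col] = frame[col].astype(str)
            unknown = ~frame[col].isin(allowed)
            if unknown.any():
                n_bucketed += int(unknown.sum())
                frame.loc[unknown, col] = "OTHER"
        if name == "prescriptions":
            supply = pd.to_numeric(frame["days_supply"], errors="coerce")
            bad = supply.isna() | (supply != supply.round()) | (supply < 1)
            if bad.any():
                row = int(bad.idxmax())
                raise ValidationError(
                    f"prescriptions: days_supply must be a positive integer "
                    f"(row {row}, value {frame['days_supply'].iloc[row]!r})")
            frame["days_supply"] = supply.astype("int64")
        if name == "labs":
            value = pd.to_numeric(frame["value"], errors="coerce")
            bad = value.isna() | (value <= 0)
            if bad.any():
                row = int(bad.idxmax())
                raise ValidationError(
                    f"labs: value must be a positive number "
                    f"(row {row}, value {frame['value'].iloc[row]!r})")
            frame["value"] = value.astype("float64")
        tables[name] = frame
    if n_bucketed:
        warnings.warn(
            f"{n_bucketed} row(s) with out-of-vocabulary codes bucketed as OTHER",
            UserWarning,
            stacklevel=2,
        )
    start, end = (pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1]))
    dataset = StudyDataset(study_start=start, study_end=end,
                           vocabulary_warnings=n_bucketed, **tables)
    return dataset.validate()


def write_dataset(dataset: StudyDataset, directory: str | Path) -> dict[str, Path]:
    """Write the five tables as CSV; the written files round-trip exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        frame = dataset.table(name).copy()
        for col in _DATE_COLUMNS[name]:
            frame[col] = frame[col].dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_dataset_dir(
    directory: str | Path,
    study_window: tuple[str | pd.Timestamp, str | pd.Timestamp],
) -> StudyDataset:
    """Convenience wrapper: read ``<table>.csv`` for each table from one directory."""
    directory = Path(directory)
    return read_dataset({t: directory / f"{t}.csv" for t in TABLE_NAMES}, study_window)
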