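"""Model/Results interface tying the pipeline stages together.

:class:`KidneyRiskModel` holds a study dataset; :meth:`KidneyRiskModel.fit`
runs cohort selection, exposure classification, outcome detection and rate
estimation, returning a :class:`KidneyRiskResults` carrying the attrition
report, the per-patient cohort and follow-up tables, the per-pattern rate
table with incidence-rate ratios versus the control, and the baseline
characteristics table.  ``summary()`` renders the whole analysis as text;
``plot_rates()`` draws the rate-ratio forest plot.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import analysis, cohort as cohort_mod, exposure, outcome
from .ehr import StudyDataset, read_dataset_dir
from .exposure import CONTROL_PATTERN, ExposurePattern


_NS_PER_DAY = 86_400_000_000_000


def _day_number(ts: pd.Timestamp) -> int:
    return int(ts.value // _NS_PER_DAY)


def _slices(sorted_ids: np.ndarray) -> dict[str, slice]:
    uniq, first = np.unique(sorted_ids, return_index=True)
    bounds = np.append(first, len(sorted_ids))
    return {u: slice(int(bounds[i]), int(bounds[i + 1])) for i, u in enumerate(uniq)}


class KidneyRiskModel:
    """Decreased-kidney-function risk analysis over DAA prescription patterns.

    Parameters
    ----------
    dataset
        A validated :class:`~daakidney.ehr.StudyDataset`.

    Examples
    --------
    >>> from daakidney import KidneyRiskModel, make_fixture
    >>> dataset, _ = make_fixture("tiny")
    >>> results = KidneyRiskModel(dataset).fit()
    >>> print(results.summary())                     # doctest: +SKIP
    """

    def __init__(self, dataset: StudyDataset):
        self.dataset = dataset

    @classmethod
    def from_csv_dir(
        cls,
        directory: str | Path,
        study_window: tuple[str, str] = ("2009-01-01", "2017-12-31"),
    ) -> "KidneyRiskModel":
        return cls(read_dataset_dir(directory, study_window))

    def fit(
        self,
        drop_threshold: int = 1,
        alpha: float = 0.05,
        ci_method: str = "exact",
    ) -> "KidneyRiskResults":
        """Run the full pipeline.

        ``drop_threshold`` 1 detects a drop of one or more eGFR categories
        from baseline (the primary outcome); 2 requires two or more (the
        sensitivity outcome).
        """
        if drop_threshold not in (1, 2):
            raise ValueError("drop_threshold must be 1 or 2")
        ds = self.dataset
        candidates, n_short = cohort_mod.find_new_users(ds)
        cand_ids = [c.patient_id for c in candidates]
        labs = ds.labs[ds.labs["patient_id"].isin(cand_ids)]
        daily = outcome.build_daily_egfr(labs, ds.patients)

        # flat integer-day views, grouped per patient, for the per-patient loop
        rx_all = (ds.prescriptions[ds.prescriptions["patient_id"].isin(cand_ids)]
                  .sort_values(["patient_id", "start_date"], kind="stable"))
        rx_drug = rx_all["drug"].to_numpy()
        rx_day = rx_all["start_date"].to_numpy("datetime64[D]").astype("int64")
        rx_supply = rx_all["days_supply"].to_numpy("int64")
        rx_slices = _slices(rx_all["patient_id"].to_numpy())
        d_day = daily["date"].to_numpy("datetime64[D]").astype("int64")
        d_val = daily["value"].to_numpy(float)
        d_cat = outcome.categorize_values(d_val)
        d_slices = _slices(daily["patient_id"].to_numpy())
        study_end_day = _day_number(ds.study_end)
        is_daa = np.isin(rx_drug, list(cohort_mod.TARGET_DAAS))

        patterns: dict[str, Optional[ExposurePattern]] = {}
        t0_days: dict[str, int] = {}
        for cand in candidates:
            t0d = _day_number(cand.t0)
            t0_days[cand.patient_id] = t0d
            anchor = cand.daa_drugs_at_t0
            if (len(anchor) > 1
                    and anchor not in exposure.PERMITTED_DAA_COMBINATIONS):
                continue
            sl = rx_slices[cand.patient_id]
            offsets = rx_day[sl] - t0d
            in_window = ((offsets >= -exposure.CONCOMITANCY_WINDOW_DAYS)
                         & (offsets <= exposure.CONCOMITANCY_WINDOW_DAYS))
            window = set(rx_drug[sl][in_window])
            patterns[cand.patient_id], _ = exposure.classify_drug_sets(anchor, window)

        final, attrition = cohort_mod.apply_exclusions(
            candidates, ds, daily_egfr=daily, patterns=patterns,
            n_insufficient_history=n_short)

        reason_order = {"treatment_end": 0, "pattern_change": 1, "study_end": 2}
        cohort_rows, fu_rows = [], []
        for entry in final:
            pid = entry.patient_id
            pattern = patterns[pid]
            t0d = t0_days[pid]
            sl = rx_slices[pid]
            drugs = rx_drug[sl]
            days = rx_day[sl]

            era = np.isin(drugs, list(pattern.episode_drugs)) & (days >= t0d)
            era_starts = days[era]
            if era_starts.size == 0 or era_starts[0] - t0d > exposure.CONCOMITANCY_WINDOW_DAYS:
                raise exposure.ClassificationError(
                    f"patient {pid!r}: no era-defining prescription at t0")
            supply_end, _n = exposure.merge_supply_days(era_starts, rx_supply[sl][era])
            raw_end = supply_end + exposure.ERA_GRACE_DAYS
            episode_end = min(raw_end, study_end_day)
            truncated = raw_end > study_end_day

            foreign = (is_daa[sl] & ~np.isin(drugs, list(pattern.anchor))
                       & (days > t0d) & (days <= episode_end))
            change_day = int(days[foreign].min()) if foreign.any() else None

            dsl = d_slices[pid]
            pdays = d_day[dsl]
            pvals = d_val[dsl]
            pcats = d_cat[dsl]
            base_window = np.nonzero((pdays >= t0d - 90) & (pdays <= t0d - 1))[0]
            if base_window.size == 0:
                raise exposure.ClassificationError(
                    f"patient {pid!r}: no baseline value (exclusion failed upstream)")
            base_idx = int(base_window[-1])  # latest day: values sorted by date
            base_val = float(pvals[base_idx])
            base_cat = int(pcats[base_idx])

            ends = [(episode_end, "study_end" if truncated else "treatment_end")]
            if change_day is not None:
                ends.append((change_day - 1, "pattern_change"))
            ends.append((study_end_day, "study_end"))
            horizon = min(day for day, _ in ends)
            reason = min((r for day, r in ends if day == horizon),
                         key=reason_order.__getitem__)
            scan = np.nonzero((pdays > t0d) & (pdays <= horizon)
                              & (pcats >= base_cat + drop_threshold))[0]
            if scan.size:
                end_day = int(pdays[scan[0]])
                outcome_status, reason = "event", "outcome"
            else:
                end_day = max(horizon, t0d)
                outcome_status = "censored"

            cohort_rows.append((pid, t0d, pattern.value, base_val, base_cat))
            fu_rows.append((pid, t0d, pattern.value, base_val, base_cat,
                            outcome_status, end_day, reason, end_day - t0d,
                            episode_end, change_day))

        cohort_frame = pd.DataFrame(
            cohort_rows, columns=["patient_id", "t0", "pattern",
                                  "baseline_egfr", "baseline_category"])
        fu_frame = pd.DataFrame(
            fu_rows, columns=["patient_id", "t0", "pattern", "baseline_egfr",
                              "baseline_category", "outcome", "end_date",
                              "end_reason", "person_days", "episode_end",
                              "change_date"])
        for frame, cols in ((cohort_frame, ["t0"]),
                            (fu_frame, ["t0", "end_date", "episode_end",
                                        "change_date"])):
            for col in cols:
                frame[col] = pd.to_datetime(frame[col], unit="D")
        cat_names = {int(c): c.name for c in outcome.KidneyCategory}
        cohort_frame["baseline_category"] = cohort_frame["baseline_category"].map(cat_names)
        fu_frame["baseline_category"] = fu_frame["baseline_category"].map(cat_names)
        if len(cohort_frame):
            meta = ds.patients.set_index("patient_id")
            cohort_frame = cohort_frame.merge(
                meta[["sex", "birth_date"]], left_on="patient_id",
                right_index=True, how="left")
            cohort_frame["age_at_t0"] = outcome.completed_years(
                cohort_frame["t0"], cohort_frame["birth_date"])
            cohort_frame = cohort_frame.drop(columns="birth_date")
        else:
            cohort_frame["sex"] = pd.Series(dtype=object)
            cohort_frame["age_at_t0"] = pd.Series(dtype="int64")

        if len(fu_frame) and CONTROL_PATTERN.value in set(fu_frame["pattern"]):
            rate_results = analysis.summarize_rates(
                fu_frame, alpha=alpha, method=ci_method)
            rates = analysis.rates_frame(rate_results)
            baseline = analysis.baseline_frame(analysis.compare_baseline(cohort_frame))
        else:
            rates = analysis.rates_frame([])
            baseline = analysis.baseline_frame([])
        return KidneyRiskResults(
            model=self, drop_threshold=drop_threshold, alpha=alpha,
            ci_method=ci_method, attrition=attrition, cohort=cohort_frame,
            follow_up=fu_frame, rates=rates, baseline=baseline)


@dataclasses.dataclass
class KidneyRiskResults:
    """Fitted results: attrition, cohort, follow-up, rates and baseline tables."""

    model: KidneyRiskModel
    drop_threshold: int
    alpha: float
    ci_method: str
    attrition: cohort_mod.AttritionReport
    cohort: pd.DataFrame
    follow_up: pd.DataFrame
    rates: pd.DataFrame
    baseline: pd.DataFrame

    def irr(self, pattern: str | ExposurePattern) -> float:
        """Point estimate of the incidence-rate ratio for one pattern."""
        code = pattern.value if isinstance(pattern, ExposurePattern) else pattern
        row = self.rates[self.rates["pattern"] == code]
        if row.empty:
            raise KeyError(f"pattern {code} not present in the fitted cohort")
        return float(row["irr"].iloc[0])

    def summary(self, masked: bool = False) -> str:
        """Text report: attrition flowchart, baseline table, rate-ratio table.

        ``masked=True`` applies the small-cell publication rule (counts
        below 10 shown as "< 10", dependent percentages as "NA").
        """
        lines = ["Decreased kidney function under DAA prescription patterns",
                 "=" * 58,
                 f"outcome: drop of >= {self.drop_threshold} eGFR categor"
                 f"{'y' if self.drop_threshold == 1 else 'ies'} from baseline; "
                 f"control: {CONTROL_PATTERN.label}",
                 "", self.attrition.format_flowchart(), ""]
        baseline = self.baseline
        if len(baseline):
            tab = baseline.copy()
            tab["age (IQR)"] = tab.apply(
                lambda r: f"{r.median_age:.0f} ({r.age_q1:.0f}-{r.age_q3:.0f})", axis=1)
            tab["eGFR (IQR)"] = tab.apply(
                lambda r: f"{r.median_egfr:.1f} ({r.egfr_q1:.1f}-{r.egfr_q3:.1f})",
                axis=1)
            tab["pct_female"] = tab["pct_female"].map(lambda v: f"{v:.1f}")
            if masked:
                tab = analysis.mask_small_cells(tab)
            tab = tab[["pattern", "label", "n_patients", "age (IQR)", "n_female",
                       "pct_female", "eGFR (IQR)", "p_age", "p_sex", "p_egfr"]]
            lines += ["Baseline characteristics (tests vs control)",
                      tab.to_string(index=False), ""]
        rates = self.rates
        if len(rates):
            tab = rates.copy()
            tab["rate"] = tab["incidence_rate"].map(
                lambda v: "NA" if np.isnan(v) else f"{v:.3f}")
            tab["IRR (95% CI)"] = tab.apply(
                lambda r: "1 (reference)" if r.pattern == CONTROL_PATTERN.value
                else (f"{r.irr:.2f} ({r.ci_low:.2f}-"
                      + (f"{r.ci_high:.2f})" if np.isfinite(r.ci_high) else "inf)")
                      if np.isfinite(r.irr) else "NA"), axis=1)
            tab["p"] = tab["p_value"].map(
                lambda v: "" if np.isnan(v) else f"{v:.4f}")
            if masked:
                tab = analysis.mask_small_cells(tab)
            tab = tab[["pattern", "label", "n_patients", "events", "person_years",
                       "rate", "IRR (95% CI)", "p", "significant"]]
            lines += ["Incidence of decreased kidney function (per person-year)",
                      tab.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
                      "", "significance criterion: p < "
                      f"{analysis.SIGNIFICANCE_LEVEL}"]
        return "\n".join(lines)

    def plot_rates(self, ax=None):
        """Forest plot of per-pattern IRRs versus the control (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        rows = self.rates[self.rates["pattern"] != CONTROL_PATTERN.value]
        rows = rows[np.isfinite(rows["irr"]) & (rows["irr"] > 0)]
        y = np.arange(len(rows))
        ax.errorbar(
            rows["irr"], y,
            xerr=[rows["irr"] - rows["ci_low"], rows["ci_high"] - rows["irr"]],
            fmt="o", color="black", ecolor="gray", capsize=3)
        ax.axvline(1.0, color="red", lw=1, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(rows["label"])
        ax.set_xscale("log")
        ax.set_xlabel("incidence-rate ratio vs " + CONTROL_PATTERN.label)
        ax.invert_yaxis()
        return ax

    def to_csv_dir(self, directory: str | Path) -> None:
        """Write attrition, cohort, follow-up, rates and baseline tables."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.attrition.to_frame().to_csv(directory / "attrition.csv", index=False)
        self.cohort.to_csv(directory / "cohort.csv", index=False)
        self.follow_up.to_csv(directory / "follow_up.csv", index=False)
        self.rates.to_csv(directory / "rates.csv", index=False)
        self.baseline.to_csv(directory / "baseline.csv", index=False)
        (directory / "report.txt").write_text(self.summary() + "\n")
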