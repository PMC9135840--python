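"""Person-time incidence rates, rate ratios versus the control pattern, and
baseline-comparison statistics.

Person-years are follow-up days divided by 365.25 (exactly 0 when follow-up
ends on the index date).  For two Poisson processes observed for fixed
person-time, conditional on the total number of events the exposed count is
binomial with success probability

    p = (IRR * PY_e) / (IRR * PY_e + PY_c),

so the incidence-rate ratio is tested and interval-estimated exactly through
the binomial: the two-sided p-value sums the probabilities of all outcomes
no more likely than the observed one under the null (IRR = 1), and the 95%
interval inverts the Clopper-Pearson interval for p.  This exact conditional
method is chosen for validity at the small event counts typical of the
per-pattern comparisons; a log-normal (Wald) interval is available for
comparison.  Rate ratios are flagged significant at the study's P < 0.01
criterion.

Baseline characteristics are compared against the control with the Wilcoxon
rank-sum test (age, baseline eGFR) and Fisher's exact test (sex), and
reported tables can mask small cells (< 10) following the source database's
publication rule.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import CONTROL_PATTERN, ExposurePattern

DAYS_PER_YEAR = 365.25
SIGNIFICANCE_LEVEL = 0.01
MASK_THRESHOLD = 10


def person_years(days: int) -> float:
    """Follow-up days divided by 365.25; 0 days is exactly 0.0 years."""
    if days < 0:
        raise ValueError(f"follow-up days must be non-negative, got {days}")
    return days / DAYS_PER_YEAR


def incidence_rate(events: int, py: float) -> float:
    """Events per person-year; NaN (not available) when person-time is zero."""
    if events < 0:
        raise ValueError(f"event count must be non-negative, got {events}")
    if py < 0:
        raise ValueError(f"person-years must be non-negative, got {py}")
    if py == 0:
        return math.nan
    return events / py


@dataclasses.dataclass
class RateResult:
    """Per-pattern incidence and its ratio to the control."""

    pattern: ExposurePattern
    n_patients: int
    events: int
    person_years: float
    incidence_rate: float
    irr: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


def _exact_conditional_p(x_e: int, n: int, p0: float) -> float:
    """Two-sided exact p: total probability of outcomes no more likely than
    the observed exposed count under Binomial(n, p0) (minimum-likelihood
    method)."""
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p0)
    return float(min(1.0, pmf[pmf <= pmf[x_e] * (1 + 1e-12)].sum()))


def _clopper_pearson(x: int, n: int, alpha: float) -> tuple[float, float]:
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def rate_ratio(
    exposed: tuple[int, float],
    control: tuple[int, float],
    alpha: float = 0.05,
    method: str = "exact",
) -> dict:
    """Incidence-rate ratio of an exposed pattern versus the control.

    Parameters
    ----------
    exposed, control
        ``(events, person_years)`` pairs; both person-year values must be
        positive.
    method
        ``"exact"`` (conditional binomial, default) or ``"wald"``
        (log-normal approximation).

    Returns a dict with ``irr``, ``ci_low``, ``ci_high``, ``p_value`` and
    ``significant`` (p below the study's 0.01 criterion).  With zero control
    events the point estimate is infinite and only the lower bound is
    informative; with zero events on both sides everything degenerates to NaN
    with p = 1.
    """
    x_e, py_e = exposed
    x_c, py_c = control
    if x_e < 0 or x_c < 0:
        raise ValueError("event counts must be non-negative")
    if py_e <= 0 or py_c <= 0:
        raise ValueError("person-years must be positive in both groups")
    if method not in ("exact", "wald"):
        raise ValueError(f"unknown method {method!r}")
    n = x_e + x_c
    if x_c == 0:
        irr = math.inf if x_e > 0 else math.nan
    else:
        irr = (x_e / py_e) / (x_c / py_c)
    if n == 0:
        return {"irr": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                "p_value": 1.0, "significant": False}
    if method == "wald":
        if x_e == 0 or x_c == 0:
            # fall back to the exact interval where the log-scale SE is undefined
            return rate_ratio(exposed, control, alpha=alpha, method="exact")
        z = stats.norm.ppf(1 - alpha / 2)
        se = math.sqrt(1 / x_e + 1 / x_c)
        log_irr = math.log(irr)
        p = 2 * stats.norm.sf(abs(math.log(irr)) / se) if irr > 0 else 1.0
        return {"irr": irr, "ci_low": math.exp(log_irr - z * se),
                "ci_high": math.exp(log_irr + z * se), "p_value": float(p),
                "significant": bool(p < SIGNIFICANCE_LEVEL)}
    p0 = py_e / (py_e + py_c)
    p_value = _exact_conditional_p(x_e, n, p0)
    p_lo, p_hi = _clopper_pearson(x_e, n, alpha)
    scale = py_c / py_e
    ci_low = (p_lo / (1 - p_lo)) * scale if p_lo < 1 else math.inf
    ci_high = (p_hi / (1 - p_hi)) * scale if p_hi < 1 else math.inf
    return {"irr": irr, "ci_low": ci_low, "ci_high": ci_high,
            "p_value": p_value, "significant": bool(p_value < SIGNIFICANCE_LEVEL)}


def summarize_rates(
    follow_up: pd.DataFrame,
    control: ExposurePattern = CONTROL_PATTERN,
    alpha: float = 0.05,
    method: str = "exact",
) -> list[RateResult]:
    """Aggregate follow-up results into per-pattern rates and IRRs.

    ``follow_up`` needs columns ``pattern`` (pattern codes), ``outcome`` and
    ``person_days``.  Patterns with no patients are omitted.  The control row
    carries IRR 1 with no test against itself.
    """
    grouped = follow_up.groupby("pattern", sort=False)
    stats_by_pattern: dict[ExposurePattern, tuple[int, int, float]] = {}
    for code, grp in grouped:
        pattern = ExposurePattern(code)
        events = int((grp["outcome"] == "event").sum())
        py = person_years(int(grp["person_days"].sum()))
        stats_by_pattern[pattern] = (len(grp), events, py)
    if control not in stats_by_pattern:
        raise ValueError(f"control pattern {control.value} absent from follow-up data")
    _, x_c, py_c = stats_by_pattern[control]
    results = []
    for pattern in ExposurePattern:
        if pattern not in stats_by_pattern:
            continue
        n, x, py = stats_by_pattern[pattern]
        rate = incidence_rate(x, py)
        if pattern is control:
            results.append(RateResult(pattern, n, x, py, rate, 1.0,
                                      math.nan, math.nan, math.nan, False))
            continue
        if py == 0 or py_c == 0:
            results.append(RateResult(pattern, n, x, py, rate, math.nan,
                                      math.nan, math.nan, math.nan, False))
            continue
        rr = rate_ratio((x, py), (x_c, py_c), alpha=alpha, method=method)
        results.append(RateResult(pattern, n, x, py, rate, rr["irr"],
                                  rr["ci_low"], rr["ci_high"], rr["p_value"],
                                  rr["significant"]))
    return results


def rates_frame(results: Sequence[RateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "pattern": r.pattern.value, "label": r.pattern.label,
            "n_patients": r.n_patients, "events": r.events,
            "person_years": r.person_years, "incidence_rate": r.incidence_rate,
            "irr": r.irr, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value, "significant": r.significant,
        } for r in results]
    )


@dataclasses.dataclass
class BaselineComparison:
    """Per-pattern baseline characteristics with tests versus the control."""

    pattern: ExposurePattern
    n_patients: int
    median_age: float
    age_iqr: tuple[float, float]
    n_female: int
    pct_female: float
    median_egfr: float
    egfr_iqr: tuple[float, float]
    p_age: float
    p_egfr: float
    p_sex: float


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) == 0 or len(y) == 0:
        return math.nan
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(min(1.0, res.pvalue))


def compare_baseline(
    cohort: pd.DataFrame,
    control: ExposurePattern = CONTROL_PATTERN,
) -> list[BaselineComparison]:
    """Baseline characteristics per pattern, tested against the control.

    ``cohort`` needs columns ``pattern``, ``age_at_t0``, ``sex`` and
    ``baseline_egfr``.  Continuous variables use the Wilcoxon rank-sum test
    (mid-ranks; exact enumeration for small untied samples, normal
    approximation with continuity correction otherwise); sex uses Fisher's
    exact test on the 2x2 female/male table.
    """
    if control.value not in set(cohort["pattern"]):
        raise ValueError(f"control pattern {control.value} absent from cohort")
    ctrl = cohort[cohort["pattern"] == control.value]
    ctrl_age = ctrl["age_at_t0"].to_numpy(float)
    ctrl_egfr = ctrl["baseline_egfr"].to_numpy(float)
    ctrl_female = int((ctrl["sex"] == "female").sum())
    ctrl_male = len(ctrl) - ctrl_female
    out = []
    for pattern in ExposurePattern:
        grp = cohort[cohort["pattern"] == pattern.value]
        if grp.empty:
            continue
        age = grp["age_at_t0"].to_numpy(float)
        egfr = grp["baseline_egfr"].to_numpy(float)
        n_female = int((grp["sex"] == "female").sum())
        _, p_sex = stats.fisher_exact(
            [[n_female, len(grp) - n_female], [ctrl_female, ctrl_male]])
        out.append(BaselineComparison(
            pattern=pattern, n_patients=len(grp),
            median_age=float(np.median(age)),
            age_iqr=(float(np.percentile(age, 25)), float(np.percentile(age, 75))),
            n_female=n_female, pct_female=100.0 * n_female / len(grp),
            median_egfr=float(np.median(egfr)),
            egfr_iqr=(float(np.percentile(egfr, 25)), float(np.percentile(egfr, 75))),
            p_age=_rank_sum_p(age, ctrl_age),
            p_egfr=_rank_sum_p(egfr, ctrl_egfr),
            p_sex=float(p_sex),
        ))
    return out


def baseline_frame(comparisons: Sequence[BaselineComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "pattern": c.pattern.value, "label": c.pattern.label,
            "n_patients": c.n_patients, "median_age": c.median_age,
            "age_q1": c.age_iqr[0], "age_q3": c.age_iqr[1],
            "n_female": c.n_female, "pct_female": c.pct_female,
            "median_egfr": c.median_egfr,
            "egfr_q1": c.egfr_iqr[0], "egfr_q3": c.egfr_iqr[1],
            "p_age": c.p_age, "p_egfr": c.p_egfr, "p_sex": c.p_sex,
        } for c in comparisons]
    )


def mask_count(n: int, threshold: int = MASK_THRESHOLD) -> str:
    """Render a patient count under the publication rule: below-threshold
    counts become ``"< 10"``."""
    return f"< {threshold}" if n < threshold else str(n)


def mask_small_cells(
    report: pd.DataFrame,
    threshold: int = MASK_THRESHOLD,
    count_columns: Optional[Sequence[str]] = None,
    dependent_columns: Optional[dict[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Apply the publication rule to a report table.

    Every value in a count column below ``threshold`` is rendered as
    ``"< 10"``; columns listed as dependent on a masked count (percentages
    derived from it) are rendered ``"NA"`` on the same rows.  Count columns
    default to those named ``n_patients``/``n_female``/``events``; dependent
    columns default to ``pct_female`` following ``n_female``.
    """
    masked = report.copy().astype(object)
    if count_columns is None:
        count_columns = [c for c in ("n_patients", "n_female", "events")
                         if c in report.columns]
    if dependent_columns is None:
        dependent_columns = {"n_female": ["pct_female"]}
    for col in count_columns:
        values = pd.to_numeric(report[col])
        small = values < threshold
        masked[col] = values.astype(int).astype(str)
        masked.loc[small, col] = f"< {threshold}"
        for dep in dependent_columns.get(col, []):
            if dep in masked.columns:
                masked.loc[small, dep] = "NA"
    return masked
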