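"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately share no code with the package: the era oracle works on
explicit day-coverage sets, the follow-up oracle enumerates calendar days one
at a time, and the eGFR oracle evaluates the estimating equation in log
space.
"""

import math


def egfr_oracle(scre: float, age: float, female: bool) -> float:
    value = math.exp(math.log(194.0) - 1.094 * math.log(scre)
                     - 0.287 * math.log(age))
    if female:
        value = math.exp(math.log(value) + math.log(0.739))
    return value


def era_oracle(prescriptions, gap=28, grace=7):
    """(first-era start, last covered day + grace) from day-coverage marking.

    ``prescriptions``: iterable of (start_day, days_supply).  Mark every
    covered day, split into runs of consecutive days, bridge holes of at most
    ``gap`` days, keep the run chain containing the earliest day, append the
    grace period.
    """
    covered = set()
    for start, supply in prescriptions:
        covered.update(range(start, start + supply))
    days = sorted(covered)
    era_start = days[0]
    era_end = days[0]
    for day in days[1:]:
        if day - era_end > gap:
            break
        era_end = day
    return era_start, era_end + grace


def follow_up_oracle(t0, episode_end, episode_truncated, change_date,
                     study_end, values_by_day, base_category, categorize,
                     drop_threshold):
    """Day-by-day enumeration of the four follow-up end conditions.

    ``values_by_day`` maps integer day -> eGFR value; ``categorize`` maps a
    value to its integer category index.  Returns
    (outcome, end_day, end_reason, person_days).
    """
    censors = [(episode_end,
                "study_end" if (episode_truncated and episode_end == study_end)
                else "treatment_end")]
    if change_date is not None:
        censors.append((change_date - 1, "pattern_change"))
    censors.append((study_end, "study_end"))
    priority = {"treatment_end": 0, "pattern_change": 1, "study_end": 2}
    horizon = min(day for day, _ in censors)
    reason = min((r for day, r in censors if day == horizon),
                 key=priority.__getitem__)
    if horizon <= t0:
        end = max(horizon, t0)
        return "censored", end, reason, end - t0
    day = t0
    while day < horizon:
        day += 1
        if day in values_by_day:
            if categorize(values_by_day[day]) >= base_category + drop_threshold:
                return "event", day, "outcome", day - t0
        if day == horizon:
            return "censored", day, reason, day - t0


def exact_irr_oracle(x_e, py_e, x_c, py_c, alpha=0.05):
    """Conditional-binomial p and CI by direct tail enumeration (scipy-free)."""
    from math import comb

    n = x_e + x_c
    p0 = py_e / (py_e + py_c)

    def pmf(k, p):
        return comb(n, k) * p ** k * (1 - p) ** (n - k)

    obs = pmf(x_e, p0)
    p_value = min(1.0, sum(pmf(k, p0) for k in range(n + 1)
                           if pmf(k, p0) <= obs * (1 + 1e-12)))

    def upper_tail(p, x):  # P(X >= x)
        return sum(pmf(k, p) for k in range(x, n + 1))

    def lower_tail(p, x):  # P(X <= x)
        return sum(pmf(k, p) for k in range(0, x + 1))

    def solve(fn, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            below = fn(mid) < target
            if below == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    # Clopper-Pearson: P(X >= x | p_lo) = alpha/2 and P(X <= x | p_hi) = alpha/2
    p_lo = 0.0 if x_e == 0 else solve(
        lambda p: upper_tail(p, x_e), alpha / 2, increasing=True)
    p_hi = 1.0 if x_e == n else solve(
        lambda p: lower_tail(p, x_e), alpha / 2, increasing=False)
    scale = py_c / py_e
    ci_low = p_lo / (1 - p_lo) * scale
    ci_high = float("inf") if p_hi == 1.0 else p_hi / (1 - p_hi) * scale
    return p_value, ci_low, ci_high
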