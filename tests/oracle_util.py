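"""Independent brute-force oracle for the consumption-pattern variables.

Implemented with plain Python loops and the :mod:`statistics` module —
deliberately sharing no code with the package's vectorised derivation — so
the two routes can be compared exactly on fixtures and small cohorts.
"""

from __future__ import annotations

import math
import statistics

from recallvar import schema as S


def _sd(vals):
    vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
    if len(vals) < 2:
        return math.nan
    return statistics.stdev(vals)


def _mean(vals):
    vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return math.nan
    return statistics.fmean(vals)


def oracle_day(rows):
    """Day-level variables from a list of item dicts (one recall day)."""
    by_time: dict[float, list[dict]] = {}
    for r in rows:
        by_time.setdefault(r[S.TIME], []).append(r)
    times = sorted(by_time)
    foods_per_ce = [len({r[S.FOOD_CODE] for r in by_time[t]}) for t in times]
    kcal_per_ce = [sum(r[S.KCAL] for r in by_time[t]) for t in times]
    gaps = [(b - a) * 60.0 for a, b in zip(times, times[1:])]
    return {
        S.ENERGY: sum(r[S.KCAL] for r in rows),
        S.CARB_G: sum(r[S.CARB] for r in rows),
        S.PROTEIN_G: sum(r[S.PROTEIN] for r in rows),
        S.FAT_G: sum(r[S.FAT] for r in rows),
        S.FIBRE_G: sum(r[S.FIBRE] for r in rows),
        S.TOTAL_GRAMS: sum(r[S.GRAMS] for r in rows),
        S.N_FOODS_DAY: float(len(rows)),
        S.FIRST_CE: times[0],
        S.N_CES: float(len(times)),
        S.MEAN_FOODS_PER_CE: _mean(foods_per_ce),
        S.SD_FOODS_PER_CE: _sd(foods_per_ce),
        S.SD_TIME_GAP: _sd(gaps),
        S.MEAN_TIME_GAP: _mean(gaps) if gaps else math.nan,
        S.SD_ENERGY_PER_CE: _sd(kcal_per_ce),
    }


def oracle_participant(rows):
    """Participant-level features (day averages + unsigned IDDs)."""
    by_day: dict[int, list[dict]] = {}
    for r in rows:
        by_day.setdefault(r[S.DAY], []).append(r)
    day_vals = {d: oracle_day(v) for d, v in sorted(by_day.items())}
    keys = next(iter(day_vals.values())).keys()
    out = {k: _mean([dv[k] for dv in day_vals.values()]) for k in keys}
    out["n_days"] = float(len(day_vals))
    if set(day_vals) == {1, 2}:
        d1, d2 = day_vals[1], day_vals[2]
        out[S.IDD_ENERGY] = abs(d1[S.ENERGY] - d2[S.ENERGY])
        out[S.IDD_FIRST_CE] = abs(d1[S.FIRST_CE] - d2[S.FIRST_CE])
        out[S.IDD_N_FOODS] = abs(d1[S.N_FOODS_DAY] - d2[S.N_FOODS_DAY])
        out[S.IDD_N_CES] = abs(d1[S.N_CES] - d2[S.N_CES])
        gap = abs(d1[S.MEAN_TIME_GAP] - d2[S.MEAN_TIME_GAP])
        out[S.IDD_MEAN_GAP] = gap
    else:
        for k in S.INTERDAY_VARS:
            out[k] = math.nan
    return out


def oracle_cohort(items_df):
    """Feature dict per participant, from a tidy item frame."""
    rows = items_df.to_dict("records")
    by_pid: dict = {}
    for r in rows:
        by_pid.setdefault(r[S.PID], []).append(r)
    return {pid: oracle_participant(v) for pid, v in by_pid.items()}


def oracle_simple_ols_residuals(y, x):
    """Closed-form residuals of y ~ 1 + x (textbook cov/var formula)."""
    n = len(y)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    slope = sxy / sxx
    intercept = my - slope * mx
    return [yi - (intercept + slope * xi) for xi, yi in zip(x, y)]
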