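"""Derivation of the 16 consumption-pattern variables.

Per recall day, the pipeline computes daily intake totals and intraday
pattern statistics; per participant, day values are averaged over the
available (1 or 2) days, unsigned interday differences (IDD) are formed for
participants with both days, and "relative" macronutrient variables are the
residuals from pooled regressions of each macronutrient's grams on total
grams consumed.

Conventions
-----------
* Standard deviations are sample SDs (n-1 denominator) and are missing when
  fewer than two values contribute; day averaging then uses the days on
  which a statistic is defined.
* Time gaps are successive event-time differences in minutes within a day;
  there is no wrap-around across midnight.
* "Distinct foods per CE" deduplicates by food code within the event;
  the day-level food count used for the IDD defaults to the raw row count
  (``distinct_day_foods=True`` switches to per-day deduplication).

Two implementations are provided: plain per-day reference functions
operating on :class:`~recallvar.ingest.RecallDay` objects, and a vectorised
table-level path (:func:`derive_day_table` / :func:`derive_features`) used by
the pipeline; the two are asserted equivalent in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import schema as S
from .ingest import ConsumptionEvent, RecallDay

__all__ = [
    "DailyTotals", "IntradayFeatures", "IDDFeatures",
    "daily_totals", "intraday_features", "count_distinct_foods",
    "interday_differences", "average_over_days",
    "derive_day_table", "derive_features", "residualize_macronutrients",
]


# ---------------------------------------------------------------------------
# per-day reference implementations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DailyTotals:
    energy_kcal: float
    carbohydrate_g: float
    protein_g: float
    fat_g: float
    fibre_g: float
    total_grams: float
    n_foods_day: float


@dataclass(frozen=True)
class IntradayFeatures:
    first_ce_time: float
    n_ces: int
    mean_foods_per_ce: float
    sd_foods_per_ce: float
    sd_time_gap_min: float
    mean_time_gap_min: float
    sd_energy_per_ce_kcal: float


@dataclass(frozen=True)
class IDDFeatures:
    idd_energy_kcal: float = math.nan
    idd_first_ce_h: float = math.nan
    idd_n_foods: float = math.nan
    idd_n_ces: float = math.nan
    idd_mean_gap_min: float = math.nan


def _sample_sd(values: Sequence[float]) -> float:
    vals = [v for v in values]
    if len(vals) < 2:
        return math.nan
    m = sum(vals) / len(vals)
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))


def count_distinct_foods(event: ConsumptionEvent) -> int:
    """Number of unique food codes within one consumption event."""
    return len({item.food_code for item in event.items})


def daily_totals(recall_day: RecallDay, distinct_day_foods: bool = False,
                 ) -> DailyTotals:
    """Sums of energy, macronutrient grams, item grams and food count."""
    items = [i for e in recall_day.events for i in e.items]
    n_foods = (len({i.food_code for i in items}) if distinct_day_foods
               else len(items))
    return DailyTotals(
        energy_kcal=sum(i.energy for i in items),
        carbohydrate_g=sum(i.carbohydrate_g for i in items),
        protein_g=sum(i.protein_g for i in items),
        fat_g=sum(i.fat_g for i in items),
        fibre_g=sum(i.fibre_g for i in items),
        total_grams=sum(i.grams for i in items),
        n_foods_day=float(n_foods),
    )


def intraday_features(recall_day: RecallDay) -> IntradayFeatures:
    """Timing and diversity statistics for one recall day.

    Gaps are successive event-time differences in minutes; SD fields use the
    n-1 denominator and are missing with fewer than two contributing values.
    """
    events = recall_day.events
    times = [e.event_time for e in events]
    foods = [count_distinct_foods(e) for e in events]
    kcal = [sum(i.energy for i in e.items) for e in events]
    gaps = [(b - a) * 60.0 for a, b in zip(times, times[1:])]
    return IntradayFeatures(
        first_ce_time=times[0],
        n_ces=len(events),
        mean_foods_per_ce=sum(foods) / len(foods),
        sd_foods_per_ce=_sample_sd(foods),
        sd_time_gap_min=_sample_sd(gaps),
        mean_time_gap_min=(sum(gaps) / len(gaps)) if gaps else math.nan,
        sd_energy_per_ce_kcal=_sample_sd(kcal),
    )


def interday_differences(day1_features: IntradayFeatures | None,
                         day1_totals: DailyTotals | None,
                         day2_features: IntradayFeatures | None,
                         day2_totals: DailyTotals | None) -> IDDFeatures:
    """Unsigned between-day differences; all-missing unless both days given.

    The interday difference in mean time gap is missing when either day has
    fewer than two events (its mean gap is then undefined).
    """
    if None in (day1_features, day1_totals, day2_features, day2_totals):
        return IDDFeatures()
    return IDDFeatures(
        idd_energy_kcal=abs(day1_totals.energy_kcal - day2_totals.energy_kcal),
        idd_first_ce_h=abs(day1_features.first_ce_time - day2_features.first_ce_time),
        idd_n_foods=abs(day1_totals.n_foods_day - day2_totals.n_foods_day),
        idd_n_ces=abs(day1_features.n_ces - day2_features.n_ces),
        idd_mean_gap_min=abs(day1_features.mean_time_gap_min
                             - day2_features.mean_time_gap_min),
    )


def average_over_days(per_day_values: Sequence[dict]) -> dict:
    """Arithmetic mean per variable over available days, skipping missing.

    A statistic defined on only one of two days averages over the days where
    it is defined (so a single-day SD carries through unchanged).
    """
    if not per_day_values:
        raise ValueError("participant has zero recall days; no features defined")
    keys = per_day_values[0].keys()
    out = {}
    for k in keys:
        vals = [d[k] for d in per_day_values if not _is_nan(d[k])]
        out[k] = sum(vals) / len(vals) if vals else math.nan
    return out


def _is_nan(v) -> bool:
    return isinstance(v, float) and math.isnan(v)


# ---------------------------------------------------------------------------
# vectorised table-level derivation
# ---------------------------------------------------------------------------

def _group_stats(idx: np.ndarray, values: np.ndarray, n_groups: int):
    """Per-group count, mean and sample SD via bincount (two-pass, stable)."""
    cnt = np.bincount(idx, minlength=n_groups).astype(float)
    sums = np.bincount(idx, weights=values, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / cnt
        dev = values - mean[idx]
        ss = np.bincount(idx, weights=dev * dev, minlength=n_groups)
        sd = np.sqrt(ss / (cnt - 1.0))
    mean[cnt == 0] = np.nan
    sd[cnt < 2] = np.nan
    return cnt, mean, sd


def derive_day_table(items: pd.DataFrame,
                     distinct_day_foods: bool = False) -> pd.DataFrame:
    """Per participant-day totals and intraday statistics.

    ``items`` is the canonical food-item frame. Returns one row per
    participant-day with the day totals and intraday features (including the
    mean time gap, needed for the interday difference).
    """
    if items.empty:
        cols = [S.PID, S.DAY, S.ENERGY, S.CARB_G, S.PROTEIN_G, S.FAT_G,
                S.FIBRE_G, S.TOTAL_GRAMS, S.N_FOODS_DAY, S.FIRST_CE, S.N_CES,
                S.MEAN_FOODS_PER_CE, S.SD_FOODS_PER_CE, S.SD_TIME_GAP,
                S.MEAN_TIME_GAP, S.SD_ENERGY_PER_CE]
        return pd.DataFrame(columns=cols)

    df = items.sort_values([S.PID, S.DAY, S.TIME, S.FOOD_CODE],
                           kind="mergesort").reset_index(drop=True)
    pid_codes, pid_values = pd.factorize(df[S.PID])
    day = df[S.DAY].to_numpy(np.int64)
    t = df[S.TIME].to_numpy(float)
    code, _ = pd.factorize(df[S.FOOD_CODE])
    n = len(df)

    new_day = np.ones(n, dtype=bool)
    new_day[1:] = (pid_codes[1:] != pid_codes[:-1]) | (day[1:] != day[:-1])
    new_event = new_day.copy()
    new_event[1:] |= t[1:] != t[:-1]
    event_id = np.cumsum(new_event) - 1
    n_events = event_id[-1] + 1
    day_id_item = np.cumsum(new_day) - 1
    n_days = day_id_item[-1] + 1

    # event-level values (events are in time order within each day)
    ev_start = np.flatnonzero(new_event)
    ev_time = t[ev_start]
    ev_day = day_id_item[ev_start]
    ev_kcal = np.bincount(event_id, weights=df[S.KCAL].to_numpy(float),
                          minlength=n_events)
    new_code = new_event.copy()
    new_code[1:] |= code[1:] != code[:-1]
    ev_distinct = np.bincount(event_id, weights=new_code.astype(float),
                              minlength=n_events)

    # day-level intraday statistics
    day_start_ev = np.ones(n_events, dtype=bool)
    day_start_ev[1:] = ev_day[1:] != ev_day[:-1]
    first_ce = ev_time[day_start_ev]
    n_ces, mean_foods, sd_foods = _group_stats(ev_day, ev_distinct, n_days)
    _, _, sd_kcal = _group_stats(ev_day, ev_kcal, n_days)
    same_day = ev_day[1:] == ev_day[:-1]
    gap_min = (ev_time[1:] - ev_time[:-1])[same_day] * 60.0
    gap_day = ev_day[1:][same_day]
    _, mean_gap, sd_gap = _group_stats(gap_day, gap_min, n_days)

    # day totals from items
    def day_sum(col):
        return np.bincount(day_id_item, weights=df[col].to_numpy(float),
                           minlength=n_days)

    day_first_item = np.flatnonzero(new_day)
    out = pd.DataFrame({
        S.PID: pid_values[pid_codes[day_first_item]],
        S.DAY: day[day_first_item],
        S.ENERGY: day_sum(S.KCAL),
        S.CARB_G: day_sum(S.CARB),
        S.PROTEIN_G: day_sum(S.PROTEIN),
        S.FAT_G: day_sum(S.FAT),
        S.FIBRE_G: day_sum(S.FIBRE),
        S.TOTAL_GRAMS: day_sum(S.GRAMS),
        S.N_FOODS_DAY: np.bincount(day_id_item, minlength=n_days).astype(float),
        S.FIRST_CE: first_ce,
        S.N_CES: n_ces,
        S.MEAN_FOODS_PER_CE: mean_foods,
        S.SD_FOODS_PER_CE: sd_foods,
        S.SD_TIME_GAP: sd_gap,
        S.MEAN_TIME_GAP: mean_gap,
        S.SD_ENERGY_PER_CE: sd_kcal,
    })
    if distinct_day_foods:
        nunique = df.groupby([S.PID, S.DAY], sort=True)[S.FOOD_CODE].nunique()
        out[S.N_FOODS_DAY] = nunique.to_numpy(float)
    return out


_AVERAGED = [S.ENERGY, S.CARB_G, S.PROTEIN_G, S.FAT_G, S.FIBRE_G,
             S.TOTAL_GRAMS, S.N_FOODS_DAY, S.FIRST_CE, S.N_CES,
             S.MEAN_FOODS_PER_CE, S.SD_FOODS_PER_CE, S.SD_TIME_GAP,
             S.MEAN_TIME_GAP, S.SD_ENERGY_PER_CE]

_IDD_SOURCE = {S.IDD_ENERGY: S.ENERGY, S.IDD_FIRST_CE: S.FIRST_CE,
               S.IDD_N_FOODS: S.N_FOODS_DAY, S.IDD_N_CES: S.N_CES,
               S.IDD_MEAN_GAP: S.MEAN_TIME_GAP}


def derive_features(items: pd.DataFrame, *, distinct_day_foods: bool = False,
                    residualize: bool = True,
                    day_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-participant feature matrix (index = participant id).

    Averages each day-level variable over the days on which it is defined,
    attaches the unsigned interday differences for participants with both
    recall days, and (by default) the pooled-residual relative macronutrient
    variables. Pass ``residualize=False`` when the pooled residualisation is
    to be run later on a larger combined sample.
    """
    if day_table is None:
        day_table = derive_day_table(items, distinct_day_foods=distinct_day_foods)
    if day_table.empty:
        raise ValueError("no recall days available; features undefined")
    g = day_table.groupby(S.PID, sort=True)
    feat = g[_AVERAGED].mean()
    feat["n_days"] = g.size()

    d1 = day_table[day_table[S.DAY] == 1].set_index(S.PID)
    d2 = day_table[day_table[S.DAY] == 2].set_index(S.PID)
    both = d1.index.intersection(d2.index)
    for idd_name, src in _IDD_SOURCE.items():
        feat[idd_name] = np.nan
        feat.loc[both, idd_name] = (d1.loc[both, src]
                                    - d2.loc[both, src]).abs()
    if residualize:
        feat = residualize_macronutrients(feat)
    return feat


def residualize_macronutrients(features: pd.DataFrame,
                               pooled: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach relative macronutrient variables (grams, pooled residuals).

    For each macronutrient, fit ordinary least squares
    ``macronutrient_g ~ 1 + total_grams`` on the pooled sample (``pooled``
    defaults to ``features`` itself; pass the both-gender frame to pool
    across genders) and store observed minus fitted. The residuals are
    uncorrelated with total grams over the pooled sample by construction;
    subsample means need not be zero.
    """
    pooled = features if pooled is None else pooled
    ok = pooled[S.TOTAL_GRAMS].notna()
    if int(ok.sum()) < 3:
        raise ValueError("residualisation needs >= 3 participants with intake data")
    g_fit = pooled.loc[ok, S.TOTAL_GRAMS].to_numpy(float)
    if np.ptp(g_fit) == 0:
        raise ValueError("total grams has zero variance; residualisation undefined")
    out = features.copy()
    g_all = features[S.TOTAL_GRAMS].to_numpy(float)
    for rel_name, raw_name in S.RELATIVE_OF.items():
        y = pooled.loc[ok, raw_name].to_numpy(float)
        X = np.column_stack([np.ones_like(g_fit), g_fit])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = beta[0] + beta[1] * g_all
        out[rel_name] = features[raw_name].to_numpy(float) - fitted
    return out
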