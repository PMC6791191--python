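"""Reading recall and participant tables, assembling consumption events,
and scoring food insecurity.

Two dialects are supported:

``tidy_csv``
    The package's own plain-text exchange format (also what the synthetic
    generator emits): a food-item file with one row per food consumed and a
    participant file with covariates, the food-insecurity score (or the ten
    item responses), BMI and a survey weight. Column names are fixed in
    :mod:`recallvar.schema`.

``nhanes_xpt``
    NHANES SAS-transport files (individual-foods recall files for days 1 and
    2, demographics, adult food-security module, body measures), read with
    :func:`pandas.read_sas`. The frame-level translation functions are public
    so they can be applied to pre-loaded tables as well.

A *consumption event* (CE) is every food or beverage reported at one unique
clock time within one recall day; event identity is exact equality of the
recorded occasion time, with no time-window merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema as S

logger = logging.getLogger(__name__)

DIALECTS = ("tidy_csv", "nhanes_xpt")

#: four-level severity cuts on the 0-10 adult score: 0 / 1-2 / 3-5 / 6-10
DEFAULT_FOURLEVEL_CUTS = (1, 3, 6)

FOURLEVEL_LABELS = ["secure", "marginal", "low", "very_low"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodItem:
    """One food or beverage row from a recall file."""

    participant_id: object
    day: int
    event_time: float           # hours from midnight, in [0, 24)
    food_code: object
    grams: float
    energy: float               # kcal
    carbohydrate_g: float
    protein_g: float
    fat_g: float
    fibre_g: float


@dataclass(frozen=True)
class ConsumptionEvent:
    """All items reported at one unique clock time in one recall day."""

    participant_id: object
    day: int
    event_time: float
    items: tuple[FoodItem, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("a consumption event must contain >= 1 item")


@dataclass(frozen=True)
class RecallDay:
    """One participant-day: events sorted by strictly increasing time."""

    participant_id: object
    day: int
    events: tuple[ConsumptionEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        times = [e.event_time for e in self.events]
        if not times:
            raise ValueError("a recall day must contain >= 1 event")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")


# ---------------------------------------------------------------------------
# food items
# ---------------------------------------------------------------------------

def read_food_items(path, dialect: str = "tidy_csv", *, day: int | None = None,
                    ) -> pd.DataFrame:
    """Read a food-item table into the canonical item frame.

    Parameters
    ----------
    path
        File path. For ``tidy_csv`` a single CSV carrying both recall days;
        for ``nhanes_xpt`` one individual-foods XPT file (``day`` selects the
        NHANES column prefix, inferred from the filename when omitted).
    dialect
        One of ``tidy_csv`` or ``nhanes_xpt``.

    Rows with a missing event time or missing energy are dropped; the count
    is logged. Times recorded as seconds from midnight (NHANES) are converted
    to fractional hours; values >= 24 h are reduced modulo 24 with a warning.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tidy_csv":
        # exact float round-trip: event identity is equality of times
        raw = pd.read_csv(path, float_precision="round_trip")
        return tidy_food_items_frame(raw)
    if day is None:
        name = path.name.upper()
        day = 2 if "DR2" in name else 1
    raw = pd.read_sas(path, format="xport")
    return nhanes_food_items_frame(raw, day=day)


def tidy_food_items_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Validate/coerce a tidy-dialect item frame (accepts ``time`` as HH:MM too)."""
    df = raw.copy()
    if S.TIME not in df.columns and "time" in df.columns:
        df[S.TIME] = _clock_to_hours(df.pop("time"))
    missing = [c for c in S.ITEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tidy_csv item file is missing columns: {missing}")
    df = df[S.ITEM_COLUMNS]
    return _finalize_items(df)


#: NHANES individual-foods variable mapping (DR1/DR2 prefix by recall day)
_NHANES_ITEM_VARS = {
    "time_seconds": "{p}_020",
    S.FOOD_CODE: "{p}IFDCD",
    S.GRAMS: "{p}IGRMS",
    S.KCAL: "{p}IKCAL",
    S.CARB: "{p}ICARB",
    S.PROTEIN: "{p}IPROT",
    S.FAT: "{p}ITFAT",
    S.FIBRE: "{p}IFIBE",
}


def nhanes_food_items_frame(raw: pd.DataFrame, day: int) -> pd.DataFrame:
    """Translate an NHANES individual-foods frame (DR1IFF/DR2IFF) to items."""
    if day not in (1, 2):
        raise ValueError("day must be 1 or 2")
    p = f"DR{day}"
    cols = {k: v.format(p=p) for k, v in _NHANES_ITEM_VARS.items()}
    absent = [v for v in cols.values() if v not in raw.columns]
    if absent:
        raise ValueError(f"NHANES foods frame lacks expected variables: {absent}")
    df = pd.DataFrame({
        S.PID: raw["SEQN"].to_numpy(),
        S.DAY: day,
        S.TIME: pd.to_numeric(raw[cols["time_seconds"]], errors="coerce") / 3600.0,
        S.FOOD_CODE: raw[cols[S.FOOD_CODE]].to_numpy(),
        S.GRAMS: pd.to_numeric(raw[cols[S.GRAMS]], errors="coerce"),
        S.KCAL: pd.to_numeric(raw[cols[S.KCAL]], errors="coerce"),
        S.CARB: pd.to_numeric(raw[cols[S.CARB]], errors="coerce"),
        S.PROTEIN: pd.to_numeric(raw[cols[S.PROTEIN]], errors="coerce"),
        S.FAT: pd.to_numeric(raw[cols[S.FAT]], errors="coerce"),
        S.FIBRE: pd.to_numeric(raw[cols[S.FIBRE]], errors="coerce"),
    })
    return _finalize_items(df)


def _finalize_items(df: pd.DataFrame) -> pd.DataFrame:
    n0 = len(df)
    df = df.dropna(subset=[S.TIME, S.KCAL])
    if len(df) < n0:
        logger.info("dropped %d item rows with missing event time or energy",
                    n0 - len(df))
    t = pd.to_numeric(df[S.TIME], errors="coerce").astype(float)
    wrapped = t >= 24.0
    if wrapped.any():
        logger.warning("reducing %d event times >= 24 h modulo 24", int(wrapped.sum()))
        t = np.mod(t, 24.0)
    df = df.assign(**{S.TIME: t, S.DAY: df[S.DAY].astype(int)})
    return df.reset_index(drop=True)


def _clock_to_hours(values: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v):
            return np.nan
        h, m = str(v).split(":")
        return int(h) + int(m) / 60.0
    return values.map(one)


# ---------------------------------------------------------------------------
# event assembly
# ---------------------------------------------------------------------------

def assemble_events(items: pd.DataFrame | Iterable[FoodItem]) -> list[RecallDay]:
    """Group food items into consumption events and recall days.

    Items are partitioned by (participant, day, event time); events within a
    day are sorted by time. Returns one :class:`RecallDay` per participant-day
    with at least one item, sorted by participant then day.
    """
    if not isinstance(items, pd.DataFrame):
        items = pd.DataFrame([i.__dict__ for i in items]).rename(columns={
            "participant_id": S.PID, "day": S.DAY, "event_time": S.TIME,
            "food_code": S.FOOD_CODE, "grams": S.GRAMS, "energy": S.KCAL,
            "carbohydrate_g": S.CARB, "protein_g": S.PROTEIN,
            "fat_g": S.FAT, "fibre_g": S.FIBRE})
    if items.empty:
        return []
    days: list[RecallDay] = []
    for (pid, day), chunk in items.groupby([S.PID, S.DAY], sort=True):
        events = []
        for t, ev in chunk.sort_values(S.TIME).groupby(S.TIME, sort=True):
            foods = tuple(
                FoodItem(pid, int(day), float(t), r[S.FOOD_CODE],
                         float(r[S.GRAMS]), float(r[S.KCAL]), float(r[S.CARB]),
                         float(r[S.PROTEIN]), float(r[S.FAT]), float(r[S.FIBRE]))
                for _, r in ev.iterrows())
            events.append(ConsumptionEvent(pid, int(day), float(t), foods))
        days.append(RecallDay(pid, int(day), tuple(events)))
    return days


# ---------------------------------------------------------------------------
# food-insecurity scoring and classification
# ---------------------------------------------------------------------------

def score_fi(item_responses: pd.DataFrame,
             affirmative: Mapping[str, Sequence] | Sequence = (1,),
             ) -> pd.Series:
    """Score the 10 adult food-security items as the count of affirmatives.

    ``item_responses`` has one column per item (at most 10). ``affirmative``
    is either one sequence of codes counted as affirmative for every item, or
    a per-column mapping. Rows with every item missing score missing; missing
    individual items simply do not count as affirmative.
    """
    if item_responses.shape[1] > 10:
        raise ValueError(
            f"adult scale has 10 items; got {item_responses.shape[1]} columns")
    if isinstance(affirmative, Mapping):
        flags = pd.DataFrame({
            c: item_responses[c].isin(affirmative[c]) for c in item_responses})
    else:
        flags = item_responses.isin(list(affirmative))
    score = flags.sum(axis=1).astype(float)
    score[item_responses.isna().all(axis=1)] = np.nan
    return score


def classify_fi(fi_score, scheme: str = "binary",
                cuts: tuple[int, int, int] = DEFAULT_FOURLEVEL_CUTS):
    """Classify 0-10 scores as secure/insecure or into four severity levels.

    Binary: score 0 -> ``secure``, score >= 1 -> ``insecure``. Four-level:
    configurable cuts defaulting to the adult-scale convention
    0 / 1-2 / 3-5 / 6-10. Missing scores yield missing categories.
    """
    scores = pd.Series(fi_score, dtype=float)
    if scheme == "binary":
        out = pd.Series(np.where(scores > 0, S.INSECURE, S.SECURE),
                        index=scores.index, dtype=object)
    elif scheme == "fourlevel":
        c1, c2, c3 = cuts
        bins = [-np.inf, c1 - 0.5, c2 - 0.5, c3 - 0.5, np.inf]
        out = pd.cut(scores, bins=bins, labels=FOURLEVEL_LABELS).astype(object)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    out[scores.isna()] = np.nan
    if np.isscalar(fi_score):
        return out.iloc[0]
    return out


# ---------------------------------------------------------------------------
# participant table
# ---------------------------------------------------------------------------

def read_participants(path, dialect: str = "tidy_csv",
                      fourlevel_cuts=DEFAULT_FOURLEVEL_CUTS) -> pd.DataFrame:
    """Read the participant table; derive fi_binary and fi_fourlevel.

    For ``tidy_csv`` the file either carries a ``fi_score`` column or ten
    ``fi_item_1`` .. ``fi_item_10`` response columns (scored with code 1 as
    affirmative). For ``nhanes_xpt`` the path is the demographics file; merge
    the food-security and body-measures tables separately with
    :func:`merge_nhanes_participants`.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "nhanes_xpt":
        return nhanes_demographics_frame(pd.read_sas(path, format="xport"))
    df = pd.read_csv(path, float_precision="round_trip")
    if S.FI_SCORE not in df.columns:
        item_cols = [c for c in df.columns if c.startswith(S.FI_ITEM_PREFIX)]
        if not item_cols:
            raise ValueError("participant file needs fi_score or fi_item_* columns")
        df[S.FI_SCORE] = score_fi(df[item_cols])
    df[S.FI_BINARY] = classify_fi(df[S.FI_SCORE], "binary")
    df[S.FI_FOURLEVEL] = classify_fi(df[S.FI_SCORE], "fourlevel", fourlevel_cuts)
    return df


#: NHANES demographic variables -> tidy names
_NHANES_DEMO_VARS = {
    S.PID: "SEQN",
    S.GENDER: "RIAGENDR",        # 1 = male, 2 = female
    S.AGE: "RIDAGEYR",
    S.INCOME: "INDFMPIR",
    S.EDUCATION: "DMDEDUC2",
    S.ETHNICITY: "RIDRETH1",
    "children_0_5": "DMDHHSZA",
    "children_6_17": "DMDHHSZB",
    S.WEIGHT: "WTMEC2YR",        # examination two-year weight (default choice)
}

#: adult food-security items and affirmative response codes
NHANES_FSQ_AFFIRMATIVE: dict[str, tuple[int, ...]] = {
    "FSD032A": (1, 2), "FSD032B": (1, 2), "FSD032C": (1, 2),
    "FSD041": (1,), "FSD052": (1, 2), "FSD061": (1,), "FSD071": (1,),
    "FSD081": (1,), "FSD092": (1,), "FSD102": (1, 2),
}


def nhanes_demographics_frame(raw: pd.DataFrame,
                              weight_var: str | None = None) -> pd.DataFrame:
    """Translate a DEMO frame; children flag from household composition."""
    cols = dict(_NHANES_DEMO_VARS)
    if weight_var is not None:
        cols[S.WEIGHT] = weight_var
    out = pd.DataFrame({k: pd.to_numeric(raw[v], errors="coerce")
                        for k, v in cols.items() if v in raw.columns})
    out[S.GENDER] = out[S.GENDER].map({1.0: "male", 2.0: "female"})
    kids = out.pop("children_0_5").fillna(0) + out.pop("children_6_17").fillna(0)
    out[S.CHILDREN] = (kids > 0).astype(int)
    return out


def nhanes_food_security_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Score the adult food-security module of an FSQ frame."""
    items = pd.DataFrame({c: pd.to_numeric(raw[c], errors="coerce")
                          for c in NHANES_FSQ_AFFIRMATIVE if c in raw.columns})
    out = pd.DataFrame({S.PID: pd.to_numeric(raw["SEQN"], errors="coerce")})
    out[S.FI_SCORE] = score_fi(
        items, {c: NHANES_FSQ_AFFIRMATIVE[c] for c in items.columns}).to_numpy()
    return out


def nhanes_body_measures_frame(raw: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        S.PID: pd.to_numeric(raw["SEQN"], errors="coerce"),
        S.BMI: pd.to_numeric(raw["BMXBMI"], errors="coerce"),
    })


def merge_nhanes_participants(demo: pd.DataFrame, fsq: pd.DataFrame,
                              bmx: pd.DataFrame,
                              fourlevel_cuts=DEFAULT_FOURLEVEL_CUTS) -> pd.DataFrame:
    """Assemble a tidy participant frame from translated NHANES tables."""
    df = demo.merge(fsq, on=S.PID, how="left").merge(bmx, on=S.PID, how="left")
    df[S.FI_BINARY] = classify_fi(df[S.FI_SCORE], "binary")
    df[S.FI_FOURLEVEL] = classify_fi(df[S.FI_SCORE], "fourlevel", fourlevel_cuts)
    return df


# ---------------------------------------------------------------------------
# analysis sample
# ---------------------------------------------------------------------------

def select_analysis_sample(participants: pd.DataFrame,
                           items: pd.DataFrame | None = None,
                           gender: str = "female",
                           min_age: float = 18) -> pd.DataFrame:
    """Restrict to the requested gender and age and count recall days.

    Participants with zero recall days are retained (they contribute to
    BMI-only analyses) but flagged via ``n_recall_days``; consumption-variable
    analyses use only participants with >= 1 day. Missing FI scores are kept
    here and handled complete-case per model downstream.
    """
    df = participants.copy()
    df = df[(df[S.GENDER] == gender) & (df[S.AGE] >= min_age)]
    if items is not None and len(items):
        days = (items.groupby(S.PID)[S.DAY].nunique()
                .rename(S.N_RECALL_DAYS))
        df = df.merge(days, left_on=S.PID, right_index=True, how="left")
        df[S.N_RECALL_DAYS] = df[S.N_RECALL_DAYS].fillna(0).astype(int)
    else:
        df[S.N_RECALL_DAYS] = 0
    logger.info("analysis sample: %d %s participants, %d with >= 1 recall day, "
                "%d with both days", len(df), gender,
                int((df[S.N_RECALL_DAYS] >= 1).sum()),
                int((df[S.N_RECALL_DAYS] == 2).sum()))
    return df.reset_index(drop=True)
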