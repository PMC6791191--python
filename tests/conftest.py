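import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import recallvar as rv
from recallvar import schema as S

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def _item(pid, day, t, code, grams, kcal, carb, prot, fat, fibre):
    return {S.PID: pid, S.DAY: day, S.TIME: t, S.FOOD_CODE: code,
            S.GRAMS: grams, S.KCAL: kcal, S.CARB: carb, S.PROTEIN: prot,
            S.FAT: fat, S.FIBRE: fibre}


@pytest.fixture(scope="session")
def two_day_items() -> pd.DataFrame:
    """A 12-item, two-day fixture for one participant (id 7).

    Day 1 has three events (one with a repeated food code), day 2 four
    events; values chosen to exercise dedup, unsigned IDDs and SD rules.
    """
    rows = [
        _item(7, 1, 7.5, 101, 120, 150, 20, 5, 4, 2),
        _item(7, 1, 7.5, 102, 250, 90, 10, 2, 1, 0.5),
        _item(7, 1, 12.25, 201, 300, 450, 45, 20, 18, 3),
        _item(7, 1, 12.25, 202, 150, 220, 30, 8, 7, 1.5),
        _item(7, 1, 12.25, 201, 50, 80, 8, 3, 4, 0.6),
        _item(7, 1, 19.0, 301, 400, 600, 70, 25, 20, 5),
        _item(7, 2, 8.0, 101, 100, 130, 18, 4, 3.5, 1.8),
        _item(7, 2, 10.5, 401, 80, 110, 12, 3, 5, 0.9),
        _item(7, 2, 10.5, 402, 60, 95, 9, 2, 4.5, 0.7),
        _item(7, 2, 15.0, 501, 350, 500, 55, 22, 15, 4),
        _item(7, 2, 15.0, 502, 200, 250, 28, 9, 8, 2),
        _item(7, 2, 21.5, 601, 330, 420, 40, 15, 16, 3.2),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with default (effectful) configuration."""
    cfg = rv.SimConfig(n_participants=400, seed=7)
    return rv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def analysis_frame():
    """Merged participant + feature frame of a mid-size synthetic cohort."""
    cfg = rv.SimConfig(n_participants=1500, seed=11)
    parts, items, truth = rv.generate_cohort(cfg)
    parts[S.FI_BINARY] = rv.classify_fi(parts[S.FI_SCORE])
    parts[S.FI_FOURLEVEL] = rv.classify_fi(parts[S.FI_SCORE], "fourlevel")
    feat = rv.derive_features(items)
    return parts.merge(feat, on=S.PID, how="left"), truth
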