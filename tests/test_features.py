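import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import recallvar as rv
from recallvar import schema as S
from recallvar.features import (DailyTotals, IntradayFeatures,
                                interday_differences, average_over_days)
from oracle_util import oracle_cohort, oracle_simple_ols_residuals


def _recall_days(items):
    return {(d.participant_id, d.day): d for d in rv.assemble_events(items)}


class TestIntradayReference:
    def test_gap_statistics_hand_computed(self):
        """Events at 7:00/12:00/19:00: gaps 300 and 420 min."""
        items = pd.DataFrame([
            {S.PID: 1, S.DAY: 1, S.TIME: t, S.FOOD_CODE: c, S.GRAMS: 100,
             S.KCAL: 200, S.CARB: 10, S.PROTEIN: 5, S.FAT: 5, S.FIBRE: 1}
            for t, c in [(7.0, 1), (12.0, 2), (19.0, 3)]])
        day = rv.assemble_events(items)[0]
        feats = rv.intraday_features(day)
        assert feats.mean_time_gap_min == pytest.approx(360.0)
        # sample SD of {300, 420} = 120 / sqrt(2)
        assert feats.sd_time_gap_min == pytest.approx(84.8528137423857)
        assert feats.first_ce_time == 7.0
        assert feats.n_ces == 3

    def test_single_event_sds_missing(self):
        items = pd.DataFrame([{S.PID: 1, S.DAY: 1, S.TIME: 9.0,
                               S.FOOD_CODE: 1, S.GRAMS: 1, S.KCAL: 1,
                               S.CARB: 0, S.PROTEIN: 0, S.FAT: 0, S.FIBRE: 0}])
        feats = rv.intraday_features(rv.assemble_events(items)[0])
        assert feats.n_ces == 1
        assert math.isnan(feats.sd_time_gap_min)
        assert math.isnan(feats.sd_foods_per_ce)
        assert math.isnan(feats.sd_energy_per_ce_kcal)

    def test_equally_spaced_events_zero_gap_sd(self):
        items = pd.DataFrame([
            {S.PID: 1, S.DAY: 1, S.TIME: t, S.FOOD_CODE: i, S.GRAMS: 1,
             S.KCAL: 100, S.CARB: 0, S.PROTEIN: 0, S.FAT: 0, S.FIBRE: 0}
            for i, t in enumerate([6.0, 10.0, 14.0, 18.0])])
        feats = rv.intraday_features(rv.assemble_events(items)[0])
        assert feats.sd_time_gap_min == pytest.approx(0.0)

    def test_distinct_food_count_dedups_by_code(self, two_day_items):
        days = _recall_days(two_day_items)
        event = days[(7, 1)].events[1]  # three items, two share a code
        assert len(event.items) == 3
        assert rv.count_distinct_foods(event) == 2
        assert rv.count_distinct_foods(days[(7, 1)].events[2]) == 1


class TestDailyTotals:
    def test_sums(self, two_day_items):
        day1 = _recall_days(two_day_items)[(7, 1)]
        tot = rv.daily_totals(day1)
        assert tot.energy_kcal == pytest.approx(150 + 90 + 450 + 220 + 80 + 600)
        assert tot.carbohydrate_g == pytest.approx(20 + 10 + 45 + 30 + 8 + 70)
        assert tot.total_grams == pytest.approx(120 + 250 + 300 + 150 + 50 + 400)
        assert tot.n_foods_day == 6

    def test_distinct_day_food_count_option(self, two_day_items):
        day1 = _recall_days(two_day_items)[(7, 1)]
        assert rv.daily_totals(day1, distinct_day_foods=True).n_foods_day == 5


class TestInterday:
    def test_identical_days_all_zero(self, two_day_items):
        days = _recall_days(two_day_items)
        d1 = days[(7, 1)]
        f1, t1 = rv.intraday_features(d1), rv.daily_totals(d1)
        idd = interday_differences(f1, t1, f1, t1)
        assert idd.idd_energy_kcal == 0
        assert idd.idd_first_ce_h == 0
        assert idd.idd_mean_gap_min == 0

    def test_symmetry_and_sign(self, two_day_items):
        days = _recall_days(two_day_items)
        f = {d: rv.intraday_features(days[(7, d)]) for d in (1, 2)}
        t = {d: rv.daily_totals(days[(7, d)]) for d in (1, 2)}
        a = interday_differences(f[1], t[1], f[2], t[2])
        b = interday_differences(f[2], t[2], f[1], t[1])
        for field in ("idd_energy_kcal", "idd_first_ce_h", "idd_n_foods",
                      "idd_n_ces", "idd_mean_gap_min"):
            va, vb = getattr(a, field), getattr(b, field)
            assert va == vb and va >= 0

    def test_one_day_returns_all_missing(self, two_day_items):
        idd = interday_differences(None, None, None, None)
        assert all(math.isnan(getattr(idd, f)) for f in
                   ("idd_energy_kcal", "idd_first_ce_h", "idd_n_foods",
                    "idd_n_ces", "idd_mean_gap_min"))

    @given(st.floats(500, 3000), st.floats(500, 3000))
    def test_unsigned_energy_difference(self, e1, e2):
        t1 = DailyTotals(e1, 0, 0, 0, 0, 0, 1)
        t2 = DailyTotals(e2, 0, 0, 0, 0, 0, 1)
        f = IntradayFeatures(8.0, 2, 1.0, 0.0, 60.0, 60.0, 0.0)
        idd = interday_differences(f, t1, f, t2)
        assert idd.idd_energy_kcal == pytest.approx(abs(e1 - e2))


class TestAveraging:
    def test_single_day_passthrough(self):
        assert average_over_days([{"x": 3.0}]) == {"x": 3.0}

    def test_two_day_mean(self):
        assert average_over_days([{"x": 1800.0}, {"x": 1600.0}])["x"] == 1700.0

    def test_sd_defined_on_one_day_only(self):
        out = average_over_days([{"sd": 12.0}, {"sd": math.nan}])
        assert out["sd"] == 12.0

    def test_zero_days_fatal(self):
        with pytest.raises(ValueError):
            average_over_days([])


class TestVectorisedAgainstOracle:
    """Table-level derivation vs the independent loop-based oracle."""

    def test_two_day_fixture_matches_oracle(self, two_day_items):
        feat = rv.derive_features(two_day_items, residualize=False)
        expected = oracle_cohort(two_day_items)[7]
        row = feat.loc[7]
        for key, val in expected.items():
            got = row[key]
            if isinstance(val, float) and math.isnan(val):
                assert math.isnan(got), key
            else:
                assert got == pytest.approx(val, rel=1e-12), key

    def test_generated_cohort_matches_oracle(self, small_cohort):
        _, items, _ = small_cohort
        sub_ids = items[S.PID].unique()[:40]
        sub = items[items[S.PID].isin(sub_ids)]
        feat = rv.derive_features(sub, residualize=False)
        expected = oracle_cohort(sub)
        for pid, exp in expected.items():
            for key, val in exp.items():
                got = feat.loc[pid, key]
                if isinstance(val, float) and math.isnan(val):
                    assert math.isnan(got), (pid, key)
                else:
                    assert got == pytest.approx(val, rel=1e-9), (pid, key)

    def test_mean_gap_identity(self, small_cohort):
        """first CE + (n_ces - 1) x mean gap / 60 lands on the last event."""
        _, items, _ = small_cohort
        days = rv.derive_day_table(items)
        last = items.groupby([S.PID, S.DAY])[S.TIME].max().to_numpy()
        multi = days[S.N_CES].to_numpy() > 1
        pred = (days[S.FIRST_CE] + (days[S.N_CES] - 1)
                * days[S.MEAN_TIME_GAP] / 60.0).to_numpy()
        assert np.allclose(pred[multi], last[multi], atol=1e-9)

    def test_empty_input(self):
        assert rv.derive_day_table(pd.DataFrame(columns=S.ITEM_COLUMNS)).empty
        with pytest.raises(ValueError):
            rv.derive_features(pd.DataFrame(columns=S.ITEM_COLUMNS))


class TestResidualisation:
    def test_perfect_linear_relation_gives_zero_residuals(self):
        g = np.array([1000.0, 2000, 3000, 4000])
        feat = pd.DataFrame({S.TOTAL_GRAMS: g, S.CARB_G: 0.1 * g + 5,
                             S.PROTEIN_G: 0.02 * g, S.FAT_G: 0.03 * g,
                             S.FIBRE_G: 0.005 * g})
        out = rv.residualize_macronutrients(feat)
        for col in (S.REL_CARB, S.REL_PROTEIN, S.REL_FAT, S.REL_FIBRE):
            assert np.allclose(out[col], 0.0, atol=1e-9)

    def test_residuals_sum_to_zero_and_orthogonal(self, analysis_frame):
        data, _ = analysis_frame
        feat = data.dropna(subset=[S.TOTAL_GRAMS])
        for col in (S.REL_CARB, S.REL_PROTEIN, S.REL_FAT, S.REL_FIBRE):
            r = feat[col].to_numpy(float)
            g = feat[S.TOTAL_GRAMS].to_numpy(float)
            assert abs(r.mean()) < 1e-8 * np.abs(feat[S.CARB_G]).mean()
            assert abs(np.corrcoef(r, g)[0, 1]) < 1e-10

    def test_toy_table_matches_closed_form_oracle(self):
        g = [1200.0, 1800, 2500, 3100, 4000]
        carb = [150.0, 210, 260, 330, 410]
        feat = pd.DataFrame({S.TOTAL_GRAMS: g, S.CARB_G: carb,
                             S.PROTEIN_G: [60.0, 70, 85, 90, 120],
                             S.FAT_G: [50.0, 65, 70, 95, 110],
                             S.FIBRE_G: [10.0, 14, 15, 22, 25]})
        out = rv.residualize_macronutrients(feat)
        exp = oracle_simple_ols_residuals(carb, g)
        assert np.allclose(out[S.REL_CARB], exp, atol=1e-9)

    def test_pooled_fit_subsample_mean_not_zero(self):
        """Residualising on a pooled sample leaves subgroup means free."""
        rng = np.random.default_rng(0)
        g = rng.uniform(1500, 4000, 200)
        group = np.arange(200) < 100
        carb = 0.1 * g + 8 * group + rng.normal(0, 5, 200)
        feat = pd.DataFrame({S.TOTAL_GRAMS: g, S.CARB_G: carb,
                             S.PROTEIN_G: carb, S.FAT_G: carb,
                             S.FIBRE_G: carb})
        out = rv.residualize_macronutrients(feat)
        assert abs(out.loc[group, S.REL_CARB].mean()) > 1.0

    def test_degenerate_inputs_fatal(self):
        tiny = pd.DataFrame({S.TOTAL_GRAMS: [1.0, 2.0],
                             S.CARB_G: [1, 2], S.PROTEIN_G: [1, 2],
                             S.FAT_G: [1, 2], S.FIBRE_G: [1, 2]})
        with pytest.raises(ValueError):
            rv.residualize_macronutrients(tiny)
        flat = pd.DataFrame({S.TOTAL_GRAMS: [2.0, 2.0, 2.0],
                             S.CARB_G: [1, 2, 3], S.PROTEIN_G: [1, 2, 3],
                             S.FAT_G: [1, 2, 3], S.FIBRE_G: [1, 2, 3]})
        with pytest.raises(ValueError):
            rv.residualize_macronutrients(flat)
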