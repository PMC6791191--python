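import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import recallvar as rv
from recallvar import schema as S
from recallvar import ingest


class TestReadFoodItems:
    def test_empty_file_header_only(self, tmp_path):
        p = tmp_path / "items.csv"
        p.write_text(",".join(S.ITEM_COLUMNS) + "\n")
        items = rv.read_food_items(p)
        assert items.empty
        assert rv.assemble_events(items) == []

    def test_clock_time_converted_to_hours(self, tmp_path):
        p = tmp_path / "items.csv"
        p.write_text(
            "participant_id,day,time,food_code,grams,kcal,"
            "carb_g,protein_g,fat_g,fibre_g\n"
            "1,1,07:30,11,100,200,10,5,5,1\n")
        items = rv.read_food_items(p)
        assert len(items) == 1
        assert items[S.TIME].iloc[0] == pytest.approx(7.5)

    def test_missing_time_or_energy_dropped(self, tmp_path, caplog):
        p = tmp_path / "items.csv"
        p.write_text(
            ",".join(S.ITEM_COLUMNS) + "\n"
            "1,1,8.0,11,100,200,1,1,1,1\n"
            "1,1,,11,100,200,1,1,1,1\n"
            "1,1,9.0,11,100,,1,1,1,1\n")
        with caplog.at_level("INFO", logger="recallvar.ingest"):
            items = rv.read_food_items(p)
        assert len(items) == 1

    def test_times_reduced_modulo_24(self, tmp_path):
        p = tmp_path / "items.csv"
        p.write_text(",".join(S.ITEM_COLUMNS) + "\n"
                     "1,1,25.5,11,100,200,1,1,1,1\n")
        items = rv.read_food_items(p)
        assert items[S.TIME].iloc[0] == pytest.approx(1.5)

    def test_unknown_dialect_and_missing_file_fatal(self, tmp_path):
        p = tmp_path / "items.csv"
        p.write_text(",".join(S.ITEM_COLUMNS) + "\n")
        with pytest.raises(ValueError):
            rv.read_food_items(p, dialect="excel")
        with pytest.raises(FileNotFoundError):
            rv.read_food_items(tmp_path / "nope.csv")


class TestNHANESFrames:
    def test_food_items_frame_translates_seconds(self):
        raw = pd.DataFrame({
            "SEQN": [1001, 1001], "DR1_020": [27000.0, 46800.0],
            "DR1IFDCD": [11111, 22222], "DR1IGRMS": [240.0, 85.0],
            "DR1IKCAL": [150.0, 95.0], "DR1ICARB": [12.0, 22.0],
            "DR1IPROT": [8.0, 1.0], "DR1ITFAT": [8.0, 0.3],
            "DR1IFIBE": [0.0, 3.7]})
        items = ingest.nhanes_food_items_frame(raw, day=1)
        assert list(items[S.TIME]) == [7.5, 13.0]
        assert list(items[S.DAY]) == [1, 1]

    def test_demographics_children_flag(self):
        raw = pd.DataFrame({
            "SEQN": [1, 2, 3], "RIAGENDR": [2, 2, 1],
            "RIDAGEYR": [34, 61, 45], "INDFMPIR": [1.2, 3.4, np.nan],
            "DMDEDUC2": [3, 5, 4], "RIDRETH1": [3, 4, 1],
            "DMDHHSZA": [1, 0, 0], "DMDHHSZB": [0, 0, 2],
            "WTMEC2YR": [25000.0, 18000.0, 30000.0]})
        demo = ingest.nhanes_demographics_frame(raw)
        assert list(demo[S.CHILDREN]) == [1, 0, 1]
        assert list(demo[S.GENDER]) == ["female", "female", "male"]

    def test_food_security_scoring_uses_item_mapping(self):
        # participant 1: three "often/sometimes true" + one yes -> 4
        # participant 2: all never/no -> 0; participant 3: all missing -> NaN
        raw = pd.DataFrame({
            "SEQN": [1, 2, 3],
            "FSD032A": [1, 3, np.nan], "FSD032B": [2, 3, np.nan],
            "FSD032C": [2, 3, np.nan], "FSD041": [1, 2, np.nan],
            "FSD052": [np.nan, 3, np.nan], "FSD061": [2, 2, np.nan],
            "FSD071": [2, 2, np.nan], "FSD081": [2, 2, np.nan],
            "FSD092": [2, 2, np.nan], "FSD102": [np.nan, 3, np.nan]})
        fsq = ingest.nhanes_food_security_frame(raw)
        assert fsq[S.FI_SCORE].tolist()[:2] == [4.0, 0.0]
        assert math.isnan(fsq[S.FI_SCORE].iloc[2])


class TestAssembleEvents:
    def _items(self, spec):
        return pd.DataFrame([
            {S.PID: pid, S.DAY: day, S.TIME: t, S.FOOD_CODE: i, S.GRAMS: 10,
             S.KCAL: 50, S.CARB: 1, S.PROTEIN: 1, S.FAT: 1, S.FIBRE: 0}
            for i, (pid, day, t) in enumerate(spec)])

    def test_grouping_by_unique_time(self):
        days = rv.assemble_events(self._items([(1, 1, 8.0), (1, 1, 8.0),
                                               (1, 1, 13.0)]))
        assert len(days) == 1
        sizes = [len(e.items) for e in days[0].events]
        assert sizes == [2, 1]

    def test_two_days_two_recall_days(self):
        days = rv.assemble_events(self._items([(1, 1, 8.0), (1, 2, 9.0)]))
        assert [(d.participant_id, d.day) for d in days] == [(1, 1), (1, 2)]

    def test_all_items_at_one_time_single_event(self):
        days = rv.assemble_events(self._items([(1, 1, 12.0)] * 5))
        assert len(days[0].events) == 1
        assert len(days[0].events[0].items) == 5

    @given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 2),
                              st.sampled_from([7.0, 8.5, 12.0, 18.25])),
                    min_size=1, max_size=20))
    def test_item_count_conserved(self, spec):
        items = self._items(spec)
        days = rv.assemble_events(items)
        total = sum(len(e.items) for d in days for e in d.events)
        assert total == len(items)


class TestFIScoring:
    def test_counting(self):
        resp = pd.DataFrame({f"q{i}": [2, 1, 1] for i in range(10)})
        resp.iloc[2, 3:] = 1  # all affirmative
        scores = rv.score_fi(resp, affirmative=(1,))
        assert scores.tolist() == [0.0, 10.0, 10.0]

    def test_partial_affirmatives(self):
        resp = pd.DataFrame([[1, 1, 1, 2, 2, 2, 2, 2, 2, 2]])
        assert rv.score_fi(resp, affirmative=(1,)).iloc[0] == 3

    def test_all_missing_scores_missing(self):
        resp = pd.DataFrame([[np.nan] * 10])
        assert math.isnan(rv.score_fi(resp).iloc[0])

    def test_too_many_items_fatal(self):
        with pytest.raises(ValueError):
            rv.score_fi(pd.DataFrame([[1] * 11]))

    def test_binary_classification(self):
        assert rv.classify_fi(0) == S.SECURE
        assert rv.classify_fi(1) == S.INSECURE
        assert rv.classify_fi(10) == S.INSECURE

    def test_fourlevel_default_cuts(self):
        got = rv.classify_fi(pd.Series([0, 1, 2, 3, 4, 5, 6, 10]),
                             scheme="fourlevel")
        assert got.tolist() == ["secure", "marginal", "marginal", "low",
                                "low", "low", "very_low", "very_low"]

    @given(st.lists(st.one_of(st.integers(0, 10), st.none()), min_size=1,
                    max_size=30))
    def test_binary_partitions_nonmissing_scores(self, scores):
        ser = pd.Series(scores, dtype=float)
        cats = rv.classify_fi(ser)
        ok = ser.notna()
        assert cats[ok].isin([S.SECURE, S.INSECURE]).all()
        assert ((cats[ok] == S.SECURE) == (ser[ok] == 0)).all()
        assert cats[~ok].isna().all()


class TestAnalysisSample:
    def _participants(self):
        return pd.DataFrame({
            S.PID: [1, 2, 3, 4],
            S.GENDER: ["female", "female", "male", "female"],
            S.AGE: [30, 17, 40, 55],
            S.FI_SCORE: [0, 2, 1, 4],
            S.BMI: [24.0, 22.0, 27.0, 31.0],
        })

    def test_gender_and_age_filters(self):
        items = pd.DataFrame({S.PID: [1, 1, 4], S.DAY: [1, 2, 1]})
        out = rv.select_analysis_sample(self._participants(), items)
        assert out[S.PID].tolist() == [1, 4]
        assert out[S.N_RECALL_DAYS].tolist() == [2, 1]

    def test_all_male_input_empty(self):
        out = rv.select_analysis_sample(self._participants(), None,
                                        gender="nonexistent")
        assert out.empty

    def test_zero_recall_day_participants_retained(self):
        items = pd.DataFrame({S.PID: [1], S.DAY: [1]})
        out = rv.select_analysis_sample(self._participants(), items)
        row4 = out[out[S.PID] == 4].iloc[0]
        assert row4[S.N_RECALL_DAYS] == 0  # BMI-only analyses keep them


class TestRoundTrip:
    def test_synthetic_csv_round_trip_preserves_event_structure(
            self, small_cohort, tmp_path):
        _, items, _ = small_cohort
        p = tmp_path / "items.csv"
        items.to_csv(p, index=False)
        back = rv.read_food_items(p)
        pd.testing.assert_frame_equal(
            back, items.reset_index(drop=True), check_dtype=False)
        a = rv.derive_day_table(items)
        b = rv.derive_day_table(back)
        pd.testing.assert_frame_equal(a, b)
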