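"""ESM container, CSV round trips, PA/NA aggregation, transition plans."""

import io

import numpy as np
import pandas as pd
import pytest

from esmdyn import (
    EsmSeries,
    aggregate_pa_na,
    build_transition_plan,
    read_esm_csv,
    write_esm_csv,
)
from conftest import make_series


def _study_csv(n_series=2, n_rows=70):
    rng = np.random.default_rng(7)
    rows = []
    for s in range(n_series):
        t = np.sort(rng.uniform(10, 22, size=n_rows)) + np.repeat(
            24 * np.arange(7), n_rows // 7
        )
        for i, ti in enumerate(t):
            rows.append(
                {
                    "series_id": f"p{s}",
                    "t_hours": ti,
                    "day": int(ti // 24),
                    "PA": rng.uniform(0, 100),
                    "NA": rng.uniform(0, 100),
                }
            )
    return pd.DataFrame(rows)


class TestCsvIo:
    def test_count_preservation(self, tmp_path):
        df = _study_csv()
        path = tmp_path / "study.csv"
        df.to_csv(path, index=False)
        series = read_esm_csv(path)
        assert len(series) == 2
        assert all(s.n == 70 for s in series)
        assert series[0].dim_names == ["PA", "NA"]

    def test_missing_cell_becomes_mask(self):
        csv = "series_id,t_hours,day,PA,NA\na,10.0,0,50,20\na,11.5,0,,30\n"
        (s,) = read_esm_csv(io.StringIO(csv))
        assert s.missing_mask[1, 0] and not s.missing_mask[1, 1]
        assert s.ratings[1, 1] == 30.0

    def test_duplicate_timestamp_rejected(self):
        csv = "series_id,t_hours,day,PA\na,10.0,0,50\na,10.0,0,60\n"
        with pytest.raises(ValueError, match="a"):
            read_esm_csv(io.StringIO(csv))

    def test_iso_datetime_converted_to_hours(self):
        csv = (
            "series_id,datetime,PA\n"
            "a,2021-03-01T10:30:00,40\n"
            "a,2021-03-01T12:00:00,40\n"
            "a,2021-03-02T10:00:00,45\n"
        )
        (s,) = read_esm_csv(io.StringIO(csv))
        np.testing.assert_allclose(s.timestamps, [10.5, 12.0, 34.0])
        np.testing.assert_array_equal(s.day_index, [0, 0, 1])

    def test_round_trip_bit_exact(self, tmp_path):
        df = _study_csv()
        p1 = tmp_path / "a.csv"
        df.to_csv(p1, index=False)
        series = read_esm_csv(p1)
        # knock out one cell to exercise missing round-tripping
        series[0].ratings[3, 1] = np.nan
        series[0].missing_mask[3, 1] = True
        p2 = tmp_path / "b.csv"
        write_esm_csv(p2, series)
        back = read_esm_csv(p2)
        for s1, s2 in zip(series, back):
            np.testing.assert_array_equal(s1.timestamps, s2.timestamps)
            np.testing.assert_array_equal(s1.missing_mask, s2.missing_mask)
            obs = ~s1.missing_mask
            np.testing.assert_array_equal(s1.ratings[obs], s2.ratings[obs])

    def test_unknown_item_column_rejected(self):
        csv = "series_id,t_hours,day,PA\na,10.0,0,50\n"
        with pytest.raises(ValueError, match="unknown"):
            read_esm_csv(io.StringIO(csv), schema={"items": ["PA", "bogus"]})


class TestAggregatePaNa:
    def _series(self, ratings, missing=None):
        n = len(ratings)
        return make_series(np.arange(n) + 10.0, [0] * n, ratings, missing)

    def test_mean_of_items(self):
        s = EsmSeries(
            "x",
            [10.0],
            [0],
            [[40.0, 60.0, 50.0, 10.0, 20.0]],
            np.zeros((1, 5), bool),
            ["happy", "relaxed", "cheerful", "sad", "anxious"],
        )
        out = aggregate_pa_na(s, ["happy", "relaxed", "cheerful"], ["sad", "anxious"])
        assert out.d == 2 and out.dim_names == ["PA", "NA"]
        assert out.ratings[0, 0] == pytest.approx(50.0)
        assert out.ratings[0, 1] == pytest.approx(15.0)

    def test_partial_missing_uses_observed_items(self):
        mask = np.array([[False, True, False, False]])
        s = EsmSeries(
            "x", [10.0], [0], [[40.0, np.nan, 60.0, 5.0]], mask, ["a", "b", "c", "n1"]
        )
        out = aggregate_pa_na(s, ["a", "b", "c"], ["n1"])
        assert out.ratings[0, 0] == pytest.approx(50.0)
        assert not out.missing_mask[0, 0]

    def test_all_missing_propagates(self):
        mask = np.array([[True, True, False]])
        s = EsmSeries("x", [10.0], [0], [[np.nan, np.nan, 7.0]], mask, ["a", "b", "n"])
        out = aggregate_pa_na(s, ["a", "b"], ["n"])
        assert out.missing_mask[0, 0]
        assert not out.missing_mask[0, 1]

    def test_empty_group_rejected(self):
        s = EsmSeries("x", [10.0], [0], [[1.0]], np.zeros((1, 1), bool), ["a"])
        with pytest.raises(ValueError):
            aggregate_pa_na(s, [], ["a"])


class TestTransitionPlan:
    def test_single_day_no_gaps(self):
        s = make_series([10.0, 11.2, 12.5], [0, 0, 0], [[1.0], [2.0], [3.0]])
        plan = build_transition_plan(s)
        assert len(plan.stationary_items) == 1
        trans = plan.transitions
        assert [t.steps for t in trans] == [1, 1]
        assert trans[0].dt_hours == pytest.approx(1.2)

    def test_missing_beep_doubles_pseudo_interval(self):
        missing = np.array([[False], [False], [True], [False]])
        s = make_series(
            [10.0, 11.0, 12.0, 13.5], [0] * 4, [[1.0], [2.0], [np.nan], [4.0]], missing
        )
        plan = build_transition_plan(s)
        (t,) = [t for t in plan.transitions if t.target == 3]
        assert t.source == 1
        assert t.steps == 2
        assert t.dt_hours == pytest.approx(2.5)

    def test_one_stationary_item_per_day(self):
        t = np.concatenate([24 * d + np.linspace(10, 22, 10) for d in range(7)])
        s = make_series(t, (t // 24).astype(int), np.ones((70, 1)) * np.arange(70)[:, None])
        plan = build_transition_plan(s)
        assert len(plan.stationary_items) == 7
        assert len(plan.transitions) == 63

    def test_every_scorable_observation_is_target_once(self, rng):
        t = np.concatenate([24 * d + np.sort(rng.uniform(10, 22, 10)) for d in range(4)])
        vals = rng.normal(size=(40, 2))
        missing = rng.random((40, 1)) < 0.2
        missing = np.repeat(missing, 2, axis=1)
        s = make_series(t, (t // 24).astype(int), vals, missing)
        plan = build_transition_plan(s)
        targets = sorted(plan.targets())
        expected = sorted(np.flatnonzero(~s.obs_missing))
        assert targets == expected

    def test_deterministic_and_idempotent(self, rng):
        t = 10.0 + np.sort(rng.uniform(0, 12, 20))
        s = make_series(t, [0] * 20, rng.normal(size=(20, 1)))
        p1 = build_transition_plan(s)
        p2 = build_transition_plan(s)
        assert [(i.kind, i.target) for i in p1.items] == [
            (i.kind, i.target) for i in p2.items
        ]

    def test_partial_dimension_missing_treated_as_fully_missing(self):
        missing = np.array([[False, False], [True, False], [False, False]])
        s = make_series(
            [10.0, 11.0, 12.0],
            [0, 0, 0],
            np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, 5.0]]),
            missing,
        )
        plan = build_transition_plan(s)
        assert plan.targets() == [0, 2]
        assert plan.transitions[0].steps == 2


def test_non_monotone_timestamps_rejected():
    with pytest.raises(ValueError, match="increasing"):
        make_series([10.0, 9.0], [0, 0], [[1.0], [2.0]])
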