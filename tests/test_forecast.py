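"""Early prediction, climatology imputation, re-trending, aggregation, scoring."""

import numpy as np
import pandas as pd
import pytest

from maizecast import calendar as cal
from maizecast import lstm, synth
from maizecast.cube import assemble_cube, broadcast_pdsi
from maizecast.features import CANONICAL_CHANNELS, DetrendScheme, retrend_yield
from maizecast.forecast import (
    aggregate,
    build_climatology,
    error_metrics,
    impute_future,
    predict_records,
    score,
    truncate_cube,
)
from maizecast.model import YieldLSTM


class TestImputeFuture:
    def _clim(self, v_rain=0.1):
        return {
            "tmax_f": np.full(214, 75.0),
            "tmin_f": np.full(214, 55.0),
            "tmean_f": np.full(214, 65.0),
            "rain_in": np.full(214, v_rain),
            "rain_max_hr_in": np.full(214, 0.05),
            "wind_mph": np.full(214, 8.0),
        }

    def test_empty_prefix_returns_climatology(self):
        clim = self._clim()
        out = impute_future({}, clim)
        np.testing.assert_array_equal(out["tmax_f"], clim["tmax_f"])
        assert len(out["cum_gdd"]) == 214

    def test_full_prefix_unchanged(self):
        rng = np.random.default_rng(0)
        obs = {
            name: arr + rng.normal(0, 0.01, 214).clip(-0.009, 0.009)
            for name, arr in self._clim().items()
        }
        out = impute_future(obs, self._clim())
        for name in obs:
            np.testing.assert_array_equal(out[name], obs[name])

    def test_cumulative_rain_stitches_observed_and_expected(self):
        v = 0.2
        clim = self._clim(v_rain=v)
        obs = {name: arr[:122].copy() for name, arr in self._clim(v_rain=0.5).items()}
        out = impute_future(obs, clim)
        observed_sum = obs["rain_in"].sum()
        assert out["cum_rain_in"][213] == pytest.approx(observed_sum + 92 * v)
        assert out["cum_rain_in"][121] == pytest.approx(observed_sum)

    def test_climatology_requires_enough_history(self, small_world):
        with pytest.raises(ValueError):
            build_climatology(
                small_world["weather"], small_world["geo"].all_counties[0],
                before_year=small_world["years"][-1], n_years=10,
            )
        clim = build_climatology(
            small_world["weather"], small_world["geo"].all_counties[0],
            before_year=small_world["years"][-1], n_years=5,
        )
        assert len(clim["tmax_f"]) == 214


@pytest.fixture(scope="module")
def fitted(small_panel, small_world):
    geo = small_world["geo"]
    years = small_world["years"]
    cube = assemble_cube(
        small_panel.subset(CANONICAL_CHANNELS), CANONICAL_CHANNELS, geo,
        train_years=years[:4],
    )
    from maizecast.cube import SplitSpec, split_by_year

    train, test = split_by_year(cube, SplitSpec(tuple(years[:4]), tuple(years[4:])))
    model = YieldLSTM(train, config=lstm.TrainConfig(hidden=4, epochs=2, patience=None))
    return model.fit(seed=0), test


class TestPredictRecords:

    def test_zero_params_predict_retrended_bias(self, fitted, small_world):
        results, test = fitted
        p = results.params
        for l in p.layers:
            l.W[:], l.U[:], l.b[:] = 0, 0, 0
        p.v[:] = 0
        p.b_out[...] = 0.0
        p.target_mean, p.target_sd = 180.0, 1.0
        scheme = DetrendScheme()
        df = predict_records(results, test, scheme)
        for _, row in df.iterrows():
            assert row["pred_bu_ac"] == pytest.approx(
                retrend_yield(180.0, row["year"], scheme), rel=1e-9
            )

    def test_base_year_prediction_equals_raw_output(self, fitted):
        results, test = fitted
        scheme = DetrendScheme(base_year=int(test.years[0]))
        df = predict_records(results, test, scheme)
        raw = results.predict(test.subset(~test.augmented))
        base_rows = df[df["year"] == scheme.base_year]
        idx = [i for i, k in enumerate(test.subset(~test.augmented).sample_keys)
               if k.year == scheme.base_year]
        np.testing.assert_allclose(base_rows["pred_bu_ac"].to_numpy(), raw[idx], rtol=1e-9)

    def test_one_year_after_base_scales_by_1_015(self, fitted):
        results, test = fitted
        year0 = int(test.years[0])
        scheme = DetrendScheme(base_year=year0 - 1)
        df = predict_records(results, test, scheme)
        raw = results.predict(test.subset(~test.augmented))
        rows = df[df["year"] == year0]
        idx = [i for i, k in enumerate(test.subset(~test.augmented).sample_keys)
               if k.year == year0]
        np.testing.assert_allclose(
            rows["pred_bu_ac"].to_numpy(), raw[idx] * 1.015, rtol=1e-9
        )

    def test_truncation_then_forward_equals_sliced(self, small_panel, small_world):
        """No hidden-state leakage: scoring a truncated cube uses only its days."""
        geo = small_world["geo"]
        years = small_world["years"]
        cube = assemble_cube(
            small_panel.subset(CANONICAL_CHANNELS), CANONICAL_CHANNELS, geo,
            train_years=years[:4],
        )
        tr = truncate_cube(cube, "aug")
        model = YieldLSTM(tr, config=lstm.TrainConfig(hidden=3, epochs=1, patience=None))
        results = model.fit(seed=1)
        preds = results.predict(tr)
        z = (tr.values - tr.norm_mean[:, None, None]) / tr.norm_sd[:, None, None]
        for j in [0, 5]:
            manual = lstm.lstm_forward(np.ascontiguousarray(z[:, :, j]), results.params)
            assert preds[j] == pytest.approx(manual, rel=1e-6)


class TestAsOfDayCube:
    def _cube(self, small_panel, small_world):
        return assemble_cube(
            small_panel.subset(CANONICAL_CHANNELS), CANONICAL_CHANNELS,
            small_world["geo"], train_years=small_world["years"][:4],
        )

    def test_prefix_kept_future_from_climatology(self, small_panel, small_world):
        from maizecast.forecast import as_of_day_cube

        cube = self._cube(small_panel, small_world)
        last = small_world["years"][-1]
        day = 100
        out = as_of_day_cube(cube, day, [last], n_hist=5)
        assert out.n_time == 214
        assert set(k.year for k in out.sample_keys) == {last}
        i_rain = cube.var_names.index("rain_in")
        j_full = [j for j, k in enumerate(cube.sample_keys) if k.year == last][0]
        unit = cube.sample_keys[j_full].unit
        j_out = [j for j, k in enumerate(out.sample_keys) if k.unit == unit][0]
        # observed prefix verbatim
        np.testing.assert_array_equal(
            out.values[i_rain, :day, j_out], cube.values[i_rain, :day, j_full]
        )
        # future = mean of the 5 prior years
        hist = [j for j, k in enumerate(cube.sample_keys)
                if k.unit == unit and k.year < last][-5:]
        clim = cube.values[i_rain, day:, hist].mean(axis=0)
        np.testing.assert_allclose(out.values[i_rain, day:, j_out], clim)
        # cumulative rain re-accumulates over the stitched series
        i_cum = cube.var_names.index("cum_rain_in")
        np.testing.assert_allclose(
            out.values[i_cum, :, j_out], np.cumsum(out.values[i_rain, :, j_out])
        )

    def test_insufficient_history_rejected(self, small_panel, small_world):
        from maizecast.forecast import as_of_day_cube

        cube = self._cube(small_panel, small_world)
        with pytest.raises(ValueError, match="prior years"):
            as_of_day_cube(cube, 50, [small_world["years"][-1]], n_hist=10)


class TestAggregate:
    def _df(self):
        return pd.DataFrame(
            {
                "state": ["S1", "S1"],
                "crd": ["S1-D1", "S1-D1"],
                "county": ["a", "b"],
                "year": [2013, 2013],
                "pred_bu_ac": [100.0, 130.0],
                "true_bu_ac": [100.0, 130.0],
            }
        )

    def test_acre_weighted_mean(self):
        geo = synth.Geography(
            states=["S1"], crds={"S1": ["S1-D1"]}, counties={"S1-D1": ["a", "b"]},
            acres={"a": 2.0, "b": 1.0},
        )
        out = aggregate(self._df(), geo, level="state")
        assert out.loc[0, "pred_bu_ac"] == pytest.approx(110.0)

    def test_equal_acres_is_simple_mean(self):
        geo = synth.Geography(
            states=["S1"], crds={"S1": ["S1-D1"]}, counties={"S1-D1": ["a", "b"]},
            acres={"a": 5.0, "b": 5.0},
        )
        out = aggregate(self._df(), geo, level="belt")
        assert out.loc[0, "pred_bu_ac"] == pytest.approx(115.0)

    def test_single_county_returns_itself(self):
        df = self._df().iloc[:1]
        out = aggregate(df, None, level="state")
        assert out.loc[0, "pred_bu_ac"] == pytest.approx(100.0)

    def test_identical_values_invariant_to_weights(self):
        df = self._df()
        df["pred_bu_ac"] = 120.0
        geo = synth.Geography(
            states=["S1"], crds={"S1": ["S1-D1"]}, counties={"S1-D1": ["a", "b"]},
            acres={"a": 17.0, "b": 3.0},
        )
        out = aggregate(df, geo, level="state")
        assert out.loc[0, "pred_bu_ac"] == pytest.approx(120.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate(self._df().iloc[:0], None)


class TestScore:
    def test_perfect_prediction(self):
        m = error_metrics([100.0, 150.0], [100.0, 150.0])
        assert m["mae"] == 0.0
        assert m["mape"] == 0.0
        assert m["within_20"] == 1.0 and m["within_30"] == 1.0

    def test_hand_example(self):
        m = error_metrics([100.0, 120.0], [110.0, 100.0])
        assert m["mae"] == pytest.approx(15.0)
        assert m["within_20"] == 1.0

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([10.0], [0.0])

    def test_band_fractions_nested(self):
        rng = np.random.default_rng(3)
        true = rng.uniform(120, 200, 50)
        pred = true + rng.normal(0, 18, 50)
        m = error_metrics(pred, true)
        assert m["within_30"] >= m["within_20"]
        if m["within_20"] == 1.0:
            assert m["mae"] <= 20.0

    def test_belt_yearly_arithmetic_matches_printed_convention(self):
        """Four-year belt series: MAE of (pred - truth) rounds to 0.83 bu/ac."""
        truth = [161.78, 175.60, 173.10, 181.09]
        pred = [162.90, 175.44, 173.40, 179.34]
        m = error_metrics(pred, truth)
        assert m["mae"] == pytest.approx(0.8325, abs=1e-10)
        assert round(m["mae"], 2) == 0.83
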