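"""The seasonal pipeline: trend, phase blocks, adaptive node search,
forecasting and serialization."""

import numpy as np
import pytest

from ftforecast import (
    SimConfig,
    TimeSeries,
    assign_seasons,
    day_of_season,
    detrend,
    eval_trend,
    fit_season,
    fit_trend,
    fit_tssf1,
    forecast_range,
    generate_series,
    load_model,
    predict,
    save_model,
)
from ftforecast.seasonal import (
    STOP_DEGENERATE,
    STOP_DENSITY,
    STOP_NMAX,
    STOP_THRESHOLD,
)
from ftforecast.partition import build_uniform_partition, is_sufficiently_dense

ALLOWED_STOPS = {STOP_THRESHOLD, STOP_DENSITY, STOP_DEGENERATE, STOP_NMAX}


@pytest.fixture(scope="module")
def fitted():
    """A model fitted on the standard 15-year synthetic series."""
    series, truth = generate_series(SimConfig(years=15, seed=11))
    model = fit_tssf1(series)
    return series, truth, model


class TestTrend:
    def test_line_recovered(self):
        t = np.arange(20)
        ts = TimeSeries(t=t, y=2 + 3 * t.astype(float))
        model = fit_trend(ts, degree=1)
        assert eval_trend(model, 0.0) == pytest.approx(2.0, abs=1e-9)
        assert eval_trend(model, 10.0) == pytest.approx(32.0, abs=1e-9)

    def test_degree_zero_is_mean(self):
        y = np.array([1.0, 5.0, 9.0])
        model = fit_trend(TimeSeries(t=np.arange(3), y=y), degree=0)
        assert eval_trend(model, 100.0) == pytest.approx(y.mean())

    def test_cubic_nested_in_degree_nine(self):
        t = np.arange(100)
        y = 1 + 0.5 * t - 0.02 * t**2 + 1e-4 * t**3
        model = fit_trend(TimeSeries(t=t, y=y), degree=9)
        resid = y - eval_trend(model, t.astype(float))
        assert np.max(np.abs(resid)) < 1e-6

    def test_underdetermined_raises(self):
        ts = TimeSeries(t=np.arange(5), y=np.ones(5))
        with pytest.raises(ValueError):
            fit_trend(ts, degree=5)

    def test_detrend_roundtrip(self):
        t = np.arange(50)
        y = 3 + 0.1 * t + np.sin(t.astype(float))
        ts = TimeSeries(t=t, y=y)
        model = fit_trend(ts, degree=3)
        resid = detrend(ts, model)
        np.testing.assert_allclose(
            resid.y + eval_trend(model, t.astype(float)), y, atol=1e-12
        )

    def test_detrend_of_exact_polynomial_is_zero(self):
        t = np.arange(40)
        y = 2 - 0.3 * t + 0.01 * t**2
        ts = TimeSeries(t=t, y=y)
        model = fit_trend(ts, degree=2)
        assert np.max(np.abs(detrend(ts, model).y)) < 1e-6


class TestSeasonAssignment:
    def test_weekly_blocks_62_days(self):
        d = np.array([1, 7, 8, 14, 15, 56, 57, 62])
        s = assign_seasons(d, 9, 62)
        np.testing.assert_array_equal(s, [1, 1, 2, 2, 3, 8, 9, 9])

    def test_block_widths_seven_by_eight_then_six(self):
        d = np.arange(1, 63)
        s = assign_seasons(d, 9, 62)
        widths = [int((s == k).sum()) for k in range(1, 10)]
        assert widths == [7] * 8 + [6]

    def test_single_season(self):
        assert (assign_seasons(np.arange(1, 63), 1, 62) == 1).all()

    def test_out_of_range_phase(self):
        with pytest.raises(ValueError):
            assign_seasons(np.array([0]), 9, 62)
        with pytest.raises(ValueError):
            assign_seasons(np.array([63]), 9, 62)

    def test_day_of_season_wraps_years(self):
        t = np.array([0, 61, 62, 63, 124, 930])
        np.testing.assert_array_equal(day_of_season(t, 62), [1, 62, 1, 2, 1, 1])


class TestFitSeason:
    def test_zero_residuals_stop_immediately(self):
        phases = np.tile(np.arange(1.0, 8.0), 5)
        fit = fit_season(phases, np.zeros_like(phases), np.full_like(phases, 30.0), 5.0)
        assert fit.stop_reason == STOP_THRESHOLD
        assert fit.n_nodes == 3
        assert fit.mad_mean == 0.0
        np.testing.assert_allclose(fit.components.c0, 0.0, atol=1e-14)
        np.testing.assert_allclose(fit.components.c1, 0.0, atol=1e-14)

    def test_two_distinct_phases_degenerate(self):
        phases = np.array([1.0, 2.0, 1.0, 2.0])
        vals = np.array([1.0, 3.0, 1.0, 3.0])
        fit = fit_season(phases, vals, vals + 10, 5.0)
        assert fit.stop_reason == STOP_DEGENERATE
        assert fit.seasonal_value(1.0) == pytest.approx(vals.mean())

    def test_linear_phase_profile_recovered(self):
        phases = np.tile(np.arange(1.0, 8.0), 15)
        vals = 0.5 * (phases - 4.0)
        fit = fit_season(phases, vals, vals + 30, threshold=1e6)
        assert fit.n_nodes == 3
        assert fit.components.c1[1] == pytest.approx(0.5, abs=1e-12)

    def test_stopping_soundness_and_termination(self):
        rng = np.random.default_rng(5)
        phases = np.tile(np.arange(1.0, 8.0), 15)
        vals = np.sin(phases) + rng.normal(0, 0.3, phases.size)
        fit = fit_season(phases, vals, vals + 30, threshold=1e-12, n_max=200)
        # impossible threshold: must end on density or the cap, never hang
        assert fit.stop_reason in (STOP_DENSITY, STOP_NMAX)
        if fit.stop_reason == STOP_DENSITY:
            nxt = build_uniform_partition(fit.phase_lo, fit.phase_hi, fit.n_nodes + 1)
            assert is_sufficiently_dense(nxt, phases)[0] is False

    def test_refinement_does_not_worsen_fit(self):
        rng = np.random.default_rng(9)
        phases = np.tile(np.arange(1.0, 8.0), 15)
        vals = 2 * np.sin(2 * np.pi * phases / 7) + rng.normal(0, 0.2, phases.size)
        fit = fit_season(phases, vals, vals + 30, threshold=0.5)
        assert fit.history[-1][1] <= fit.history[0][1]

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            fit_season([], [], [], 5.0)


class TestPipeline:
    def test_white_noise_recovers_mean_and_null_season(self):
        rng = np.random.default_rng(3)
        sigma, level = 1.0, 10.0
        t = np.arange(620)
        y = level + rng.normal(0, sigma, t.size)
        model = fit_tssf1(
            TimeSeries(t=t, y=y), degree=0, n_seasons=1, threshold=1e6
        )
        assert eval_trend(model.trend, 0.0) == pytest.approx(y.mean())
        # components average >= m/(2n) noise values each
        c0 = model.seasons[0].components.c0
        assert np.max(np.abs(c0)) < 4 * sigma / np.sqrt(620 / 6)

    def test_trend_only_series_has_null_seasonal_terms(self):
        series, _ = generate_series(
            SimConfig(years=10, noise_sd=0.0, seasonal_profile=np.zeros(62))
        )
        model = fit_tssf1(series, degree=4)
        for sf in model.seasons:
            assert sf.stop_reason == STOP_THRESHOLD
            assert np.max(np.abs(sf.components.c0)) < 1e-6

    def test_structure_of_full_fit(self, fitted):
        _, _, model = fitted
        assert len(model.seasons) == 9
        assert {sf.stop_reason for sf in model.seasons} <= ALLOWED_STOPS
        assert [sf.season for sf in model.seasons] == list(range(1, 10))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_tssf1(TimeSeries(t=np.arange(10), y=np.zeros(10)), degree=2)


class TestPredict:
    def test_null_seasonal_model_predicts_trend(self):
        series, _ = generate_series(
            SimConfig(years=10, noise_sd=0.0, seasonal_profile=np.zeros(62))
        )
        model = fit_tssf1(series, degree=4)
        t = np.arange(620, 682)
        np.testing.assert_allclose(
            predict(model, t), eval_trend(model.trend, t.astype(float)), atol=1e-6
        )

    def test_same_phase_differs_by_trend_only(self, fitted):
        _, _, model = fitted
        t1, t2 = 10, 10 + 62 * 3  # same phase, three years apart
        lhs = predict(model, t2) - predict(model, t1)
        rhs = eval_trend(model.trend, float(t2)) - eval_trend(model.trend, float(t1))
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_noiseless_training_predictions_match_fit_diagnostics(self):
        series, _ = generate_series(SimConfig(years=15, noise_sd=0.0))
        model = fit_tssf1(series)
        pred = predict(model, series.t)
        resid = np.abs(pred - series.y)
        d = day_of_season(series.t, 62)
        s = assign_seasons(d, 9, 62)
        for sf in model.seasons:
            mask = s == sf.season
            achieved = 100 * resid[mask].sum() / series.y[mask].sum()
            assert achieved == pytest.approx(sf.mad_mean, abs=1e-6)

    def test_forecast_range(self, fitted):
        _, _, model = fitted
        out = forecast_range(model, 930, 992)
        assert len(out) == 62
        np.testing.assert_allclose(out.y, predict(model, out.t))
        assert len(forecast_range(model, 930, 930)) == 0

    def test_decomposition_depends_on_phase_only(self, fitted):
        _, _, model = fitted
        for t0 in (0, 5, 33, 61):
            terms = [
                predict(model, t0 + 62 * j)
                - eval_trend(model.trend, float(t0 + 62 * j))
                for j in range(20)
            ]
            np.testing.assert_allclose(terms, terms[0], atol=1e-12)


class TestSerialization:
    def test_roundtrip_is_bit_identical(self, fitted, tmp_path):
        _, _, model = fitted
        path = tmp_path / "model.json"
        save_model(model, path)
        clone = load_model(path)
        t = np.arange(0, 992)
        np.testing.assert_array_equal(predict(model, t), predict(clone, t))
        assert clone.config == model.config
        assert [s.stop_reason for s in clone.seasons] == [
            s.stop_reason for s in model.seasons
        ]


class TestTimeSeriesValidation:
    def test_rejects_nonincreasing_time(self):
        with pytest.raises(ValueError):
            TimeSeries(t=np.array([1, 1, 2]), y=np.zeros(3))

    def test_rejects_nonfinite_values(self):
        with pytest.raises(ValueError):
            TimeSeries(t=np.arange(3), y=np.array([1.0, np.nan, 2.0]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            TimeSeries(t=np.arange(3), y=np.zeros(4))
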