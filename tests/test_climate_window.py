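"""Lapse correction, window aggregation, GLM fitting and the window scan."""

import numpy as np
import pandas as pd
import pytest

from capreosex.climate_window import (
    WINDOW_AXIS,
    WindowSpec,
    assign_height_class,
    effect_curve,
    fit_binomial_glm,
    lapse_correct,
    muri_model,
    scan_windows,
    window_aggregate,
)
from capreosex.synthetic_data import (
    SimulationConfig,
    simulate_offspring,
    simulate_weather,
)


class TestLapseCorrection:
    @pytest.mark.parametrize(
        "t, hasl, expected",
        [(10, 0, 10.0), (10, 1000, 3.5), (-2, 250, -3.625)],
    )
    def test_values(self, t, hasl, expected):
        assert lapse_correct(t, hasl) == pytest.approx(expected)

    def test_linear_decreasing_in_elevation(self):
        e = np.linspace(0, 2000, 50)
        t = lapse_correct(10.0, e)
        assert (np.diff(t) < 0).all()
        assert np.allclose(np.diff(t, 2), 0.0)


class TestHeightClasses:
    @pytest.mark.parametrize(
        "elev, label",
        [(0, "<250"), (249.9, "<250"), (250, "250-500"), (499.9, "250-500"),
         (500, "500-750"), (750, ">=750"), (900, ">=750")],
    )
    def test_half_open_binning(self, elev, label):
        assert assign_height_class(elev) == label

    def test_negative_elevation_errors(self):
        with pytest.raises(ValueError):
            assign_height_class(-1.0)


def _weather_frame(values):
    """values: {(year, month): temperature}; precipitation constant."""
    rows = [
        {"year": y, "month": m, "temperature_c": t, "precipitation_mm": 50.0}
        for (y, m), t in values.items()
    ]
    return pd.DataFrame(rows)


class TestWindowAggregate:
    def test_single_month_window(self):
        w = _weather_frame({(2000, 10): 7.5})
        assert window_aggregate(w, WindowSpec(4, 4), 2001) == 7.5

    def test_constant_series(self):
        vals = {(2000, m): 3.0 for m in range(6, 13)}
        vals.update({(2001, 1): 3.0, (2001, 2): 3.0})
        w = _weather_frame(vals)
        assert window_aggregate(w, WindowSpec(4, 8), 2001) == pytest.approx(3.0)

    def test_jan_feb_mean(self):
        w = _weather_frame({(2001, 1): 2.0, (2001, 2): 4.0})
        assert window_aggregate(w, WindowSpec(7, 8), 2001) == pytest.approx(3.0)

    def test_missing_month_named_in_error(self):
        w = _weather_frame({(2001, 1): 2.0})
        with pytest.raises(ValueError, match="year=2001, month=2"):
            window_aggregate(w, WindowSpec(7, 8), 2001)

    def test_axis_crosses_year_boundary(self):
        # index 0-6 -> Jun..Dec of t-1; 7-8 -> Jan..Feb of t
        assert WINDOW_AXIS[0] == (6, -1)
        assert WINDOW_AXIS[6] == (12, -1)
        assert WINDOW_AXIS[7] == (1, 0)

    def test_window_enumeration_count(self):
        m = len(WINDOW_AXIS)
        windows = [(lo, hi) for lo in range(m) for hi in range(lo, m)]
        assert len(windows) == m * (m + 1) // 2 == 45


class TestBinomialGlm:
    def test_intercept_only_closed_form(self):
        fit = fit_binomial_glm(np.array([1] * 60 + [0] * 40))
        assert fit.params[0] == pytest.approx(np.log(60 / 40), abs=1e-8)

    def test_planted_coefficients_recovered(self):
        rng = np.random.default_rng(1)
        n = 20_000
        x = rng.normal(0, 1.5, n)
        xc = x - x.mean()
        true = np.array([-0.1, 0.05, 0.02])
        eta = true[0] + true[1] * xc + true[2] * xc**2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_binomial_glm(y, pd.DataFrame({"x": x}), quadratic=True)
        for b, se, t in zip(fit.params, fit.bse, true):
            assert abs(b - t) < 1.96 * se

    def test_loglik_matches_grid_oracle(self):
        """At n = 20 the IRLS maximum matches a brute-force grid maximizer."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = (rng.random(20) < 0.5).astype(float)
        fit = fit_binomial_glm(y, pd.DataFrame({"x": x}), quadratic=False)
        xc = x - x.mean()

        def llf(a, b):
            eta = a + b * xc
            return float((y * eta - np.log1p(np.exp(eta))).sum())

        best = -np.inf
        a_grid = np.linspace(fit.params[0] - 1, fit.params[0] + 1, 201)
        b_grid = np.linspace(fit.params[1] - 1, fit.params[1] + 1, 201)
        for a in a_grid:
            for b in b_grid:
                best = max(best, llf(a, b))
        assert fit.log_likelihood == pytest.approx(best, abs=1e-4)
        assert fit.log_likelihood >= best - 1e-10

    def test_single_sex_errors(self):
        with pytest.raises(ValueError, match="single-sex"):
            fit_binomial_glm(np.ones(50))

    def test_separation_detected(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(float)
        with pytest.raises(RuntimeError):
            fit_binomial_glm(y, pd.DataFrame({"x": x}))

    def test_nesting_never_increases_deviance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 500)
        y = (rng.random(500) < 1 / (1 + np.exp(-0.3 * x))).astype(float)
        cov = pd.DataFrame({"x": x})
        null = fit_binomial_glm(y)
        linear = fit_binomial_glm(y, cov, quadratic=False)
        quad = fit_binomial_glm(y, cov, quadratic=True)
        assert quad.deviance <= linear.deviance + 1e-8
        assert linear.deviance <= null.deviance + 1e-8

    def test_effect_curve_bounds_bracket_prediction(self):
        rng = np.random.default_rng(5)
        x = rng.normal(5, 2, 2000)
        y = (rng.random(2000) < 0.5).astype(float)
        fit = fit_binomial_glm(y, pd.DataFrame({"x": x}), quadratic=True)
        curve = effect_curve(fit, np.linspace(0, 10, 11))
        assert ((curve["ci_low"] <= curve["proportion_female"])
                & (curve["proportion_female"] <= curve["ci_high"])).all()


class TestMuriModel:
    def test_twelve_covariates(self, small_config, small_weather):
        off = simulate_offspring(small_config, small_weather)
        fit = muri_model(off, small_weather)
        assert len(fit.params) == 13  # intercept + 6 T + 6 P
        assert sum(n.startswith("T_") for n in fit.names) == 6
        assert sum(n.startswith("P_") for n in fit.names) == 6

    def test_planted_december_effect_recovered(self, small_weather):
        """A planted T_Dec(t-1) coefficient is recovered within 2 SE."""
        rng = np.random.default_rng(8)
        years = rng.choice(np.arange(1995, 2015), 50_000)
        dec = {
            int(y): float(
                small_weather.query("year == @y - 1 and month == 12")["temperature_c"].iloc[0]
            )
            for y in np.unique(years)
        }
        x = np.array([dec[int(y)] for y in years])
        y = (rng.random(len(x)) < 1 / (1 + np.exp(-0.1 * (x - x.mean())))).astype(int)
        off = pd.DataFrame(
            {"site_id": "x", "year": years, "sex": y,
             "elevation_m": 100.0, "est_age_days": 8}
        )
        fit = muri_model(off, small_weather)
        i = fit.names.index("T_Dec(t-1)")
        assert abs(fit.params[i] - 0.1) < 2 * fit.bse[i]

    def test_constant_weather_rank_deficient(self, small_config, small_weather):
        off = simulate_offspring(small_config, small_weather)
        flat = small_weather.copy()
        flat["temperature_c"] = 5.0
        flat["precipitation_mm"] = 50.0
        with pytest.raises(ValueError, match="rank-deficient"):
            muri_model(off, flat)


@pytest.fixture(scope="module")
def scanned():
    cfg = SimulationConfig(seed=7, years=(1995, 2014), n_per_year=300)
    weather = simulate_weather(cfg)
    off = simulate_offspring(cfg, weather)
    return cfg, off, weather, scan_windows(off, weather, by_height_class=False)


class TestScanWindows:
    def test_table_has_null_plus_45_windows(self, scanned):
        _, _, _, res = scanned
        per_class = res.table.groupby("height_class").size()
        assert (per_class == 46).all()

    def test_weights_normalized(self, scanned):
        _, _, _, res = scanned
        sums = res.table.groupby("height_class")["weight"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_recovers_planted_window(self, scanned):
        cfg, _, _, res = scanned
        assert res.best_window["all"].jaccard(cfg.planted_window) >= 0.6

    def test_consensus_agrees_across_classes(self):
        cfg = SimulationConfig(seed=19, years=(1995, 2014), n_per_year=600,
                               elevation_mix=(0.25, 0.25, 0.25, 0.25))
        weather = simulate_weather(cfg)
        off = simulate_offspring(cfg, weather)
        res = scan_windows(off, weather, by_height_class=True)
        assert res.consensus_window is not None
        assert res.consensus_window.jaccard(cfg.planted_window) >= 0.6

    def test_temperature_shift_leaves_delta_aicc_invariant(self, scanned):
        cfg, off, weather, res = scanned
        shifted = weather.copy()
        shifted["temperature_c"] = shifted["temperature_c"] + 5.0
        res2 = scan_windows(off, shifted, by_height_class=False)
        merged = res.table.merge(
            res2.table, on=["height_class", "open_idx", "close_idx"], suffixes=("", "_s")
        )
        assert np.allclose(merged["delta_aicc"], merged["delta_aicc_s"], atol=1e-6)

    def test_small_class_skipped_with_warning(self, small_config, small_weather):
        off = simulate_offspring(small_config, small_weather)
        off = off[off["elevation_m"] < 750]  # thin out the top class
        top = off.head(10).copy()
        top["elevation_m"] = 800.0
        off = pd.concat([off, top])
        with pytest.warns(UserWarning, match="skipped"):
            res = scan_windows(off, small_weather, by_height_class=True)
        assert ">=750" in res.skipped_classes

    def test_needs_two_years(self, small_weather):
        off = pd.DataFrame(
            {"year": 2000, "sex": [0, 1] * 50, "elevation_m": 100.0,
             "est_age_days": 8, "site_id": "x"}
        )
        with pytest.raises(ValueError, match="2 birth years"):
            scan_windows(off, small_weather)
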