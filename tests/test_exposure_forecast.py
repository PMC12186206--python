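import numpy as np
import pandas as pd
import pytest

from sanburden.exposure_forecast import (
    ArimaFit,
    ArimaOrder,
    fit_arima,
    forecast_composition,
    forecast_series,
    select_order,
)
from sanburden.panel_io import SanitationShares
from sanburden.synthetic_world import SanitationTrendConfig, WorldConfig, generate_sanitation


def _ar1(n, phi=0.6, seed=0, mean=0.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for t in range(1, n):
        x[t] = phi * (x[t - 1]) + rng.standard_normal()
    return x + mean


class TestSelectOrder:
    def test_white_noise_modal_selection_is_the_null_model(self):
        # selection is checked distributionally: information criteria overfit
        # individual noise draws, but the mode over replicates must be (0,0,0)
        from collections import Counter

        counts = Counter(
            select_order(np.random.default_rng(seed).standard_normal(200),
                         ArimaOrder(2, 1, 2))
            for seed in range(9)
        )
        assert counts.most_common(1)[0][0] == ArimaOrder(0, 0, 0)

    def test_noiseless_linear_trend_forces_differencing(self):
        order = select_order(np.linspace(0.0, 1.0, 50))
        assert order.d >= 1

    def test_constant_series_maps_to_intercept_only_model(self):
        assert select_order(np.full(30, 0.4)) == ArimaOrder(0, 0, 0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="length"):
            select_order(np.arange(5.0))

    def test_ar1_is_the_modal_selection(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            order = select_order(_ar1(300, seed=seed), ArimaOrder(2, 1, 2))
            hits += order == ArimaOrder(1, 0, 0)
        assert hits > n_rep / 2


class TestFitArima:
    def test_ar1_coefficient_recovered(self):
        fit = fit_arima(_ar1(500, seed=1), ArimaOrder(1, 0, 0))
        assert abs(fit.ar_coefs[0] - 0.6) < 0.1
        assert fit.sigma2 > 0

    def test_random_walk_on_constant_series_has_zero_variance_flat_forecast(self):
        fit = fit_arima(np.full(30, 2.0), ArimaOrder(0, 1, 0))
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-8)
        fc = forecast_series(fit, 4)
        assert np.allclose(fc["mean"], 2.0, atol=1e-8)

    def test_mle_agrees_with_least_squares_oracle_on_long_ar1(self):
        # independent closed-form oracle: OLS of x_t on x_{t-1} after demeaning
        x = _ar1(2000, phi=0.7, seed=11, mean=3.0)
        fit = fit_arima(x, ArimaOrder(1, 0, 0))
        z = x - x.mean()
        phi_ols = float(z[1:] @ z[:-1] / (z[:-1] @ z[:-1]))
        assert abs(fit.ar_coefs[0] - phi_ols) < 0.02
        assert abs(fit.ar_coefs[0] - 0.7) < 0.05

    def test_nonsense_orders_rejected(self):
        with pytest.raises(ValueError):
            fit_arima(np.arange(30.0), ArimaOrder(-1, 0, 0))
        with pytest.raises(ValueError):
            fit_arima(np.arange(4.0), ArimaOrder(2, 1, 2))

    def test_stationarity_invariant_enforced_on_the_fit_record(self):
        with pytest.raises(ValueError, match="stationar"):
            ArimaFit(ArimaOrder(1, 0, 0), np.array([1.01]), np.array([]), 0.0,
                     1.0, 0.0, "x")


class TestForecastSeries:
    def test_random_walk_forecast_is_last_value(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.standard_normal(100))
        fit = fit_arima(x, ArimaOrder(0, 1, 0))
        fc = forecast_series(fit, 6)
        assert np.allclose(fc["mean"], x[-1], atol=1e-8)

    def test_ar1_forecast_decays_geometrically_to_the_mean(self):
        x = _ar1(400, phi=0.6, seed=5, mean=10.0)
        fit = fit_arima(x, ArimaOrder(1, 0, 0))
        fc = forecast_series(fit, 8)
        phi, mu = fit.ar_coefs[0], fit.const
        closed = mu + phi ** np.arange(1, 9) * (x[-1] - mu)
        assert np.abs(fc["mean"].to_numpy() - closed).max() < 1e-6

    def test_interval_width_monotone_in_horizon(self):
        x = _ar1(200, seed=7)
        fit = fit_arima(x, ArimaOrder(1, 0, 0))
        fc = forecast_series(fit, 10)
        width = (fc["hi"] - fc["lo"]).to_numpy()
        assert (np.diff(width) >= -1e-12).all()

    def test_nonpositive_horizon_rejected(self):
        fit = fit_arima(_ar1(100), ArimaOrder(1, 0, 0))
        with pytest.raises(ValueError):
            forecast_series(fit, 0)


def _history(sewer=0.2, improved=0.4, unimproved=0.4, years=range(2000, 2021)):
    return SanitationShares(pd.DataFrame(
        {"country": "AAA", "year": list(years), "sewer": sewer,
         "improved": improved, "unimproved": unimproved}))


class TestForecastComposition:
    def test_constant_history_forecasts_the_constant(self):
        fc = forecast_composition(_history(), horizon=5)
        got = fc.data[["sewer", "improved", "unimproved"]].to_numpy()
        assert np.abs(got - np.array([0.2, 0.4, 0.4])).max() < 1e-6

    def test_transform_mode_point_forecasts_sum_to_one(self):
        panel, _ = generate_sanitation(WorldConfig(n_countries=3, year_end=2020, seed=44))
        for c in panel.data.country.unique():
            sub = SanitationShares(panel.data[panel.data.country == c]
                                   .reset_index(drop=True))
            fc = forecast_composition(sub, horizon=10)
            sums = fc.data[["sewer", "improved", "unimproved"]].sum(axis=1)
            assert np.abs(sums - 1.0).max() < 1e-9

    def test_declining_unimproved_does_not_jump_up_at_first_step(self):
        cfg = WorldConfig(n_countries=3, year_end=2020, seed=15,
                          sanitation_trend=SanitationTrendConfig(logit_noise=0.0))
        panel, _ = generate_sanitation(cfg)
        for c in panel.data.country.unique():
            sub = panel.data[panel.data.country == c].sort_values("year")
            fc = forecast_composition(
                SanitationShares(sub.reset_index(drop=True)), horizon=5)
            first = fc.data.sort_values("year")["unimproved"].iloc[0]
            assert first <= sub["unimproved"].iloc[-1] + 1e-9

    def test_bounds_bracket_points_and_stay_in_unit_interval(self):
        panel, _ = generate_sanitation(WorldConfig(n_countries=2, year_end=2020, seed=16))
        for c in panel.data.country.unique():
            sub = SanitationShares(panel.data[panel.data.country == c]
                                   .reset_index(drop=True))
            fc = forecast_composition(sub, horizon=8).data
            for cat in ("sewer", "improved", "unimproved"):
                assert (fc[cat + "_lo"] <= fc[cat] + 1e-12).all()
                assert (fc[cat] <= fc[cat + "_hi"] + 1e-12).all()
                assert (fc[cat + "_lo"] >= -1e-12).all()
                assert (fc[cat + "_hi"] <= 1 + 1e-12).all()

    def test_independent_mode_renormalizes_and_is_flagged(self):
        panel, _ = generate_sanitation(WorldConfig(n_countries=1, year_end=2020, seed=18))
        fc = forecast_composition(SanitationShares(panel.data), horizon=5,
                                  mode="independent")
        sums = fc.data[["sewer", "improved", "unimproved"]].sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-9
        assert (fc.data["mode"] == "independent").all()

    def test_short_history_and_unknown_mode_rejected(self):
        short = _history(years=range(2000, 2005))
        with pytest.raises(ValueError, match="10"):
            forecast_composition(short, horizon=3)
        with pytest.raises(ValueError, match="mode"):
            forecast_composition(_history(), horizon=3, mode="bogus")
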