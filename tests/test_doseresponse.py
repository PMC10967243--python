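"""Asymptotic temperature-response model: rate law, forward model, fitting."""

import numpy as np
import pandas as pd
import pytest

from stemtherm.doseresponse import (DoseResponseParams, accumulate_heights,
                                    fit_asymptotic, fit_linear_slope,
                                    predict_heights, response_rate)
from stemtherm.simdata import gen_temperature_series, simulate_plot_height


def brute_force_height(params, hour_times, temps, window, t):
    """Independent hourly accumulation oracle (explicit loop)."""
    total = 0.0
    t_a, t_b = window
    for h, T in zip(hour_times, temps):
        if t_a <= h < min(t, t_b):
            if T > params.T_min:
                total += params.r_max * (1 - np.exp(-np.exp(params.lrc)
                                                    * (T - params.T_min)))
    return params.H0 + total / 1000.0


class TestResponseRate:
    @pytest.mark.parametrize("T,expected", [
        (4.0, 0.0),                       # zero at the base temperature
        (3.0, 0.0),                       # and below it
        (5.0, 1.0 - np.exp(-1.0)),        # closed form one degree above
    ])
    def test_closed_forms(self, T, expected):
        p = DoseResponseParams(T_min=4.0, r_max=1.0, lrc=0.0)
        assert response_rate(p, T) == pytest.approx(expected, abs=1e-12)

    def test_saturates_to_rmax(self):
        p = DoseResponseParams(T_min=4.0, r_max=0.8, lrc=1.0)
        assert response_rate(p, 54.0) == pytest.approx(0.8, abs=1e-6 * 0.8)

    def test_monotone_in_temperature_and_parameters(self):
        T = np.linspace(-5, 30, 200)
        p = DoseResponseParams(T_min=4.0, r_max=0.8, lrc=2.0)
        r = response_rate(p, T)
        assert np.all(np.diff(r) >= -1e-12)
        # increasing r_max scales rates up
        r_hi = response_rate(DoseResponseParams(4.0, 1.2, 2.0), T)
        assert np.all(r_hi >= r)
        # increasing lrc raises r(T) for every T > T_min
        r_steep = response_rate(DoseResponseParams(4.0, 0.8, 3.0), T)
        above = T > 4.0
        assert np.all(r_steep[above] >= r[above] - 1e-12)


class TestForwardModel:
    def test_height_constant_before_window(self):
        temps = gen_temperature_series(60, (10, 10), 0.0, 0.0)
        p = DoseResponseParams(4.0, 0.8, 3.0, H0=0.15)
        h = accumulate_heights(p, temps.times, temps.values, (30, 50),
                               [5.0, 10.0, 29.9])
        assert np.allclose(h, 0.15)

    def test_no_growth_at_tmin(self):
        temps = gen_temperature_series(60, (4.0, 4.0), 0.0, 0.0)
        p = DoseResponseParams(4.0, 0.8, 3.0, H0=0.2)
        h = accumulate_heights(p, temps.times, temps.values, (10, 50),
                               [20.0, 40.0, 55.0])
        assert np.allclose(h, 0.2)

    def test_constant_temperature_closed_form(self):
        # constant T: gain over dt days inside the window = r(T)*24*dt/1000 m
        temps = gen_temperature_series(60, (12.0, 12.0), 0.0, 0.0)
        p = DoseResponseParams(4.0, 0.8, 3.0, H0=0.1)
        r = response_rate(p, 12.0)
        h = accumulate_heights(p, temps.times, temps.values, (10, 50),
                               [20.0, 30.0])
        assert h[1] - h[0] == pytest.approx(r * 24 * 10 / 1000.0, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        temps = gen_temperature_series(50, (2, 18), 6.0, 1.5, 0.6, seed=9)
        for _ in range(5):
            p = DoseResponseParams(T_min=rng.uniform(-2, 8),
                                   r_max=rng.uniform(0.3, 1.5),
                                   lrc=rng.uniform(0.5, 4),
                                   H0=rng.uniform(0, 0.3))
            w = sorted(rng.uniform(5, 45, 2))
            ts = np.sort(rng.uniform(0, 49, 6))
            got = accumulate_heights(p, temps.times, temps.values, w, ts)
            want = [brute_force_height(p, temps.times, temps.values, w, t)
                    for t in ts]
            assert np.allclose(got, want, atol=1e-9)

    def test_uncovered_times_error(self):
        temps = gen_temperature_series(40, (5, 15), 0.0, 0.0)
        p = DoseResponseParams(4.0, 0.8, 3.0)
        with pytest.raises(ValueError, match="coverage"):
            accumulate_heights(p, temps.times, temps.values, (5, 35), [60.0])

    def test_simulator_shares_the_accumulation_model(self):
        temps = gen_temperature_series(60, (2, 18), 6.0, 1.0, 0.6, seed=4)
        truth = pd.Series({"T_min": 4.0, "r_max": 0.8, "lrc": 3.0,
                           "start": 15.0, "stop": 45.0})
        sched = np.arange(10.0, 55.0, 3.0)
        hs = simulate_plot_height(truth, temps, sched, 0.0, 0.0, H0=0.15)
        p = DoseResponseParams(4.0, 0.8, 3.0, H0=0.15)
        pred = predict_heights(p, temps, (15.0, 45.0), sched)
        assert np.allclose(hs.heights, pred, atol=1e-12)


class TestFitAsymptotic:
    def _simulate(self, noise_sd, seed=0):
        temps = gen_temperature_series(110, (3, 17), 5.0, 1.0, 0.7, seed=seed)
        truth = pd.Series({"T_min": 4.0, "r_max": 0.8, "lrc": 3.0,
                           "start": 25.0, "stop": 90.0})
        sched = np.arange(20.0, 95.0, 3.0)
        hs = simulate_plot_height(truth, temps, sched, 0.0, noise_sd,
                                  H0=0.15, seed=seed + 1)
        return temps, hs

    def test_noise_free_recovery(self):
        temps, hs = self._simulate(0.0, seed=12)
        fit = fit_asymptotic(hs.times, hs.heights, temps.times, temps.values,
                             (25.0, 90.0), seed=0)
        assert fit.status == "ok"
        assert abs(fit.params.T_min - 4.0) < 0.05
        assert abs(fit.params.r_max - 0.8) / 0.8 < 0.01
        assert abs(fit.params.lrc - 3.0) < 0.05

    def test_loglik_at_optimum_beats_truth(self):
        temps, hs = self._simulate(0.0, seed=13)
        fit = fit_asymptotic(hs.times, hs.heights, temps.times, temps.values,
                             (25.0, 90.0), n_starts=4, seed=0)
        mask = (hs.times >= 25.0) & (hs.times <= 90.0)
        truth_pred = accumulate_heights(
            DoseResponseParams(4.0, 0.8, 3.0, 0.15), temps.times, temps.values,
            (25.0, 90.0), hs.times[mask])
        ssr_truth = np.sum((truth_pred - hs.heights[mask]) ** 2)
        ssr_fit = fit.params.sigma ** 2 * fit.n_obs
        assert ssr_fit <= ssr_truth + 1e-6

    def test_saturated_temperatures_flag_weak_identifiability(self):
        # all hours far above T_min: r_max recoverable, T_min/lrc flagged
        temps = gen_temperature_series(110, (20, 24), 1.0, 0.3, 0.5, seed=5)
        truth = pd.Series({"T_min": 4.0, "r_max": 0.8, "lrc": 3.0,
                           "start": 25.0, "stop": 90.0})
        sched = np.arange(20.0, 95.0, 3.0)
        hs = simulate_plot_height(truth, temps, sched, 0.0, 0.0, H0=0.15)
        fit = fit_asymptotic(hs.times, hs.heights, temps.times, temps.values,
                             (25.0, 90.0), n_starts=4, seed=0)
        assert fit.status == "ok"
        assert abs(fit.params.r_max - 0.8) / 0.8 < 0.05
        assert any("T_min" in f for f in fit.flags)
        assert any("lrc" in f for f in fit.flags)

    def test_too_few_points_and_flat_series(self):
        temps = gen_temperature_series(60, (5, 15), 3.0, 1.0, 0.5, seed=2)
        few = fit_asymptotic([10, 13, 16], [0.1, 0.2, 0.3], temps.times,
                             temps.values, (5, 55))
        assert few.status == "failed"
        t = np.arange(10.0, 40.0, 3.0)
        flat = fit_asymptotic(t, np.full_like(t, 0.2), temps.times,
                              temps.values, (5, 55))
        assert flat.status == "degenerate"

    def test_recovery_degrades_gracefully_with_narrow_span(self):
        # RMSE of T_min non-increasing as the temperature span widens
        # spans centered on the mid-range: a narrow warm span never reaches
        # the base temperature, so T_min is poorly determined there
        spans = {5.0: [], 10.0: [], 20.0: []}
        truth = pd.Series({"T_min": 4.0, "r_max": 0.8, "lrc": 3.0,
                           "start": 25.0, "stop": 90.0})
        sched = np.arange(20.0, 95.0, 3.0)
        for span, errs in spans.items():
            for s in range(6):
                temps = gen_temperature_series(
                    110, (10.0 - span / 2, 10.0 + span / 2), span / 8,
                    0.5, 0.5, seed=600 + s)
                hs = simulate_plot_height(truth, temps, sched, 0.0, 0.005,
                                          H0=0.15, seed=s)
                fit = fit_asymptotic(hs.times, hs.heights, temps.times,
                                     temps.values, (25.0, 90.0),
                                     n_starts=6, seed=s)
                errs.append((fit.params.T_min - 4.0) ** 2)
        rmse = [np.sqrt(np.mean(spans[s])) for s in (5.0, 10.0, 20.0)]
        assert rmse[2] <= rmse[0] + 1e-9


class TestLinearSlope:
    def test_exact_linear_truth(self):
        # construct heights whose interval rates are exactly a + b * meanT
        temps = gen_temperature_series(60, (5, 15), 4.0, 1.0, 0.6, seed=8)
        a, b = 0.1, 0.04
        times = np.arange(10.0, 50.0, 3.0)
        heights = [0.2]
        for k in range(len(times) - 1):
            i0 = int(np.searchsorted(temps.times, times[k]))
            i1 = int(np.searchsorted(temps.times, times[k + 1]))
            mt = temps.values[i0:i1].mean()
            rate = a + b * mt                       # mm/h
            heights.append(heights[-1] + rate * (times[k + 1] - times[k])
                           * 24 / 1000.0)
        fit = fit_linear_slope(times, np.array(heights), temps.times,
                               temps.values, (10.0, 50.0))
        assert fit.lm_slope == pytest.approx(b, abs=1e-6)
        assert fit.n_intervals == len(times) - 1

    def test_constant_temperature_errors(self):
        temps = gen_temperature_series(60, (10, 10), 0.0, 0.0)
        times = np.arange(10.0, 30.0, 3.0)
        with pytest.raises(ValueError, match="slope undefined"):
            fit_linear_slope(times, times / 100.0, temps.times, temps.values,
                             (10.0, 30.0))

    def test_noise_leaves_expected_slope_unchanged(self):
        temps = gen_temperature_series(60, (5, 15), 4.0, 1.0, 0.6, seed=8)
        a, b = 0.1, 0.04
        times = np.arange(10.0, 50.0, 3.0)
        base = [0.2]
        for k in range(len(times) - 1):
            i0 = int(np.searchsorted(temps.times, times[k]))
            i1 = int(np.searchsorted(temps.times, times[k + 1]))
            mt = temps.values[i0:i1].mean()
            base.append(base[-1] + (a + b * mt) * 3 * 24 / 1000.0)
        base = np.array(base)
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(60):
            noisy = base + rng.standard_normal(len(base)) * 0.004
            fit = fit_linear_slope(times, noisy, temps.times, temps.values,
                                   (10.0, 50.0))
            slopes.append(fit.lm_slope)
        assert np.mean(slopes) == pytest.approx(b, rel=0.05)
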