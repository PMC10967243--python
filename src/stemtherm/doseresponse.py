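"""Asymptotic temperature dose-response model for stem elongation.

The hourly elongation rate is modeled as an asymptotic-regression curve

    r(T) = r_max * (1 - exp(-exp(lrc) * (T - T_min)))   for T > T_min,
    r(T) = 0                                            otherwise,

with r_max the maximum (optimal-temperature) elongation rate in mm h-1,
T_min the base temperature in degC at and below which the rate is zero, and
lrc the log rate constant controlling the steepness of the rise.  Plant
height over an elongation window [t_a, t_b) accumulates the hourly rates:

    H(t) = H0 + (1/1000) * sum over hours h with t_a <= t_h < min(t, t_b)
           of r(T_h)   [meters],

where t_h is the hour's start time in days since sowing and each hour's
growth is credited at its recorded temperature.  Parameters are estimated by
maximum likelihood under i.i.d. Gaussian residuals on the observed heights
(the residual SD is profiled analytically), with bound constraints and
multistart initialization.  A linear benchmark regresses interval growth
rates on interval mean temperatures (``lm_slope``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc


@dataclass
class DoseResponseParams:
    """Parameters of the asymptotic temperature response."""

    T_min: float      # degC
    r_max: float      # mm / h
    lrc: float        # log(1/degC)
    H0: float = 0.0   # m, height at window start
    sigma: float = 0.0  # m, residual SD

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class DoseResponseFit:
    params: DoseResponseParams
    loglik: float
    status: str                  # "ok" | "degenerate" | "failed"
    flags: list = field(default_factory=list)
    frac_hours_below_tmin: float = float("nan")
    frac_hours_curved: float = float("nan")
    n_obs: int = 0
    multistart_logliks: list = field(default_factory=list)


@dataclass
class LinearResponseFit:
    lm_slope: float              # mm h-1 degC-1
    intercept: float             # mm h-1
    r_squared: float
    rates: np.ndarray            # mm h-1, one per interval
    mean_temps: np.ndarray       # degC, one per interval
    n_intervals: int = 0

    def __post_init__(self):
        self.n_intervals = len(self.rates)


def response_rate(params: DoseResponseParams, T) -> np.ndarray:
    """Hourly elongation rate in mm h-1 at temperature(s) ``T``.

    Continuous at T_min; zero at and below it.
    """
    T = np.asarray(T, float)
    x = np.exp(params.lrc) * (T - params.T_min)
    r = params.r_max * (-np.expm1(-np.clip(x, 0.0, None)))
    return np.where(T > params.T_min, r, 0.0)


def _hour_index(hour_times: np.ndarray, t: float) -> int:
    """Number of hours whose start time is strictly before ``t``."""
    return int(np.searchsorted(hour_times, t, side="left"))


def accumulate_heights(params: DoseResponseParams, hour_times: np.ndarray,
                       temps: np.ndarray, window, times) -> np.ndarray:
    """Predicted heights (m) at ``times`` under the accumulation model.

    ``hour_times`` are hour start times in fractional days since sowing;
    growth is credited for every hour h with window[0] <= t_h < min(t, window[1]).
    """
    hour_times = np.asarray(hour_times, float)
    temps = np.asarray(temps, float)
    times = np.atleast_1d(np.asarray(times, float))
    t_a, t_b = float(window[0]), float(window[1])
    if times.max() > hour_times[-1] + 1.0 / 24.0 + 1e-9:
        raise ValueError(
            f"prediction times extend to day {times.max():.2f} but temperature "
            f"coverage ends at day {hour_times[-1]:.2f}")
    r = response_rate(params, temps)
    csum = np.concatenate([[0.0], np.cumsum(r)])
    i_a = _hour_index(hour_times, t_a)
    i_t = np.searchsorted(hour_times, np.minimum(times, t_b), side="left")
    i_t = np.maximum(i_t, i_a)
    return params.H0 + (csum[i_t] - csum[i_a]) / 1000.0


def predict_heights(params: DoseResponseParams, temps, window, times) -> np.ndarray:
    """Convenience wrapper taking a TemperatureSeries-like object.

    ``temps`` must expose ``.times`` (hourly, days) and ``.values`` (degC).
    """
    return accumulate_heights(params, temps.times, temps.values, window, times)


DEFAULT_BOUNDS = {
    "T_min": (-5.0, 15.0),
    "r_max": (1e-3, 3.0),
    "lrc": (0.0, 6.0),
}


def fit_asymptotic(times, heights, hour_times, temps, window,
                   bounds: Optional[dict] = None, n_starts: int = 8,
                   seed: int = 0, min_points: int = 5) -> DoseResponseFit:
    """Maximum-likelihood fit of the asymptotic model to one height series.

    Parameters ``(T_min, r_max, lrc, H0)`` are optimized by L-BFGS-B from
    ``n_starts`` Latin-hypercube initializations (deterministic given
    ``seed``); the Gaussian residual SD is profiled.  Only measurements
    inside ``window`` are used.
    """
    times = np.asarray(times, float)
    heights = np.asarray(heights, float)
    hour_times = np.asarray(hour_times, float)
    temps = np.asarray(temps, float)
    t_a, t_b = float(window[0]), float(window[1])
    mask = (times >= t_a) & (times <= t_b + 1e-9)
    t_obs, y_obs = times[mask], heights[mask]
    n = len(t_obs)
    if n < min_points:
        return DoseResponseFit(
            params=DoseResponseParams(0.0, 1e-3, 0.0), loglik=-np.inf,
            status="failed", flags=[f"only {n} in-window points"], n_obs=n)
    if np.ptp(y_obs) < 1e-6:
        return DoseResponseFit(
            params=DoseResponseParams(0.0, 1e-3, 0.0), loglik=-np.inf,
            status="degenerate", flags=["flat height series"], n_obs=n)

    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    r_lo, r_hi = b["r_max"]
    h_lo = min(y_obs.min() - 0.3, 0.0)
    h_hi = y_obs.min() + 0.3
    lb2 = np.array([b["T_min"][0], b["lrc"][0]])
    ub2 = np.array([b["T_min"][1], b["lrc"][1]])

    # restrict temperatures to the accumulation span once
    i_a = _hour_index(hour_times, t_a)
    i_b = _hour_index(hour_times, min(t_obs.max(), t_b))
    T_win = temps[i_a:i_b]
    idx_t = np.searchsorted(hour_times, np.minimum(t_obs, t_b), side="left") - i_a
    idx_t = np.clip(idx_t, 0, len(T_win))
    ones = np.ones(n)

    # For fixed (T_min, lrc) the model is linear in (H0, r_max); profile
    # them by least squares.  SSR in mm^2 keeps the objective well scaled.
    def prof(phi):
        T_min, lrc = phi
        x = np.exp(lrc) * (T_win - T_min)
        r = -np.expm1(-np.clip(x, 0.0, None))
        r[T_win <= T_min] = 0.0
        csum = np.concatenate([[0.0], np.cumsum(r)])
        S = csum[idx_t] / 1000.0
        A = np.column_stack([ones, S])
        coef, *_ = np.linalg.lstsq(A, y_obs, rcond=None)
        H0, r_max = float(coef[0]), float(coef[1])
        if not (r_lo <= r_max <= r_hi) or not (h_lo <= H0 <= h_hi):
            r_max = float(np.clip(r_max, r_lo, r_hi))
            H0 = float(np.clip((y_obs - r_max * S).mean(), h_lo, h_hi))
        d = (H0 + r_max * S - y_obs) * 1000.0
        return float(d @ d), (H0, r_max)

    def objective(phi):
        if np.any(phi < lb2) or np.any(phi > ub2):
            return 1e12
        return prof(phi)[0]

    # coarse deterministic grid plus seeded Latin-hypercube starts
    tm_grid = np.linspace(lb2[0], ub2[0], 25)
    lrc_grid = np.linspace(lb2[1], ub2[1], 13)
    cand = [(objective((tm, lr)), (tm, lr))
            for tm in tm_grid for lr in lrc_grid]
    cand.sort(key=lambda c: c[0])
    starts = [np.array(c[1]) for c in cand[:max(n_starts, 2)]]
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=2, seed=rng)
    starts.extend(lb2 + sampler.random(max(n_starts // 2, 1)) * (ub2 - lb2))

    best_x, best_f = None, np.inf
    logliks = []
    for s in starts:
        res = optimize.minimize(objective, s, method="Nelder-Mead",
                                options={"maxiter": 600, "fatol": 1e-16,
                                         "xatol": 1e-10})
        s2 = max(res.fun * 1e-6 / n, 1e-18)
        logliks.append(-0.5 * n * (np.log(2 * np.pi * s2) + 1.0))
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_x is None or not np.isfinite(best_f):
        return DoseResponseFit(
            params=DoseResponseParams(0.0, 1e-3, 0.0), loglik=-np.inf,
            status="failed", flags=["all starts failed"], n_obs=n)

    # Nelder-Mead can stall on the T_min/lrc likelihood ridge; restart the
    # simplex from the incumbent until no further improvement
    for _ in range(4):
        res = optimize.minimize(objective, best_x, method="Nelder-Mead",
                                options={"maxiter": 600, "fatol": 1e-16,
                                         "xatol": 1e-10})
        if res.fun < best_f - 1e-12:
            best_x, best_f = res.x, res.fun
        else:
            break

    ssr_m2, (H0, r_max) = prof(best_x)
    ssr_m2 *= 1e-6
    T_min, lrc = float(best_x[0]), float(best_x[1])
    sigma = float(np.sqrt(max(ssr_m2 / n, 0.0)))
    params = DoseResponseParams(T_min=float(T_min), r_max=float(max(r_max, 1e-6)),
                                lrc=float(lrc), H0=float(H0), sigma=sigma)
    s2 = max(ssr_m2 / n, 1e-18)
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

    # identifiability diagnostics on in-window hours
    flags = []
    frac_below = float(np.mean(T_win < T_min + 1.0)) if len(T_win) else np.nan
    r_all = response_rate(params, T_win)
    frac_curved = float(np.mean((r_all > 0.1 * params.r_max)
                                & (r_all < 0.9 * params.r_max))) if len(T_win) else np.nan
    if frac_below < 0.05:
        flags.append("T_min weakly identified")
        flags.append("lrc weakly identified")  # curvature unseen without cold hours
    if frac_curved < 0.05 and "lrc weakly identified" not in flags:
        flags.append("lrc weakly identified")

    return DoseResponseFit(params=params, loglik=float(loglik), status="ok",
                           flags=flags, frac_hours_below_tmin=frac_below,
                           frac_hours_curved=frac_curved, n_obs=n,
                           multistart_logliks=logliks)


def fit_linear_slope(times, heights, hour_times, temps, window) -> LinearResponseFit:
    """Linear temperature-response benchmark.

    For each consecutive in-window measurement pair, the growth rate
    (mm h-1) is regressed by OLS on the mean hourly temperature of the
    interval; the slope is ``lm_slope``.
    """
    times = np.asarray(times, float)
    heights = np.asarray(heights, float)
    hour_times = np.asarray(hour_times, float)
    temps = np.asarray(temps, float)
    t_a, t_b = float(window[0]), float(window[1])
    mask = (times >= t_a) & (times <= t_b + 1e-9)
    t_obs, y_obs = times[mask], heights[mask]
    if len(t_obs) < 4:
        raise ValueError("need at least 3 in-window intervals (4 measurements)")
    rates = np.diff(y_obs) * 1000.0 / (np.diff(t_obs) * 24.0)
    mean_t = np.empty(len(rates))
    for k in range(len(rates)):
        i0 = _hour_index(hour_times, t_obs[k])
        i1 = max(_hour_index(hour_times, t_obs[k + 1]), i0 + 1)
        mean_t[k] = temps[i0:i1].mean()
    if np.ptp(mean_t) < 1e-12:
        raise ValueError("slope undefined: no temperature variance across intervals")
    A = np.column_stack([np.ones_like(mean_t), mean_t])
    coef, *_ = np.linalg.lstsq(A, rates, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((rates - pred) ** 2))
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return LinearResponseFit(lm_slope=float(coef[1]), intercept=float(coef[0]),
                             r_squared=r2, rates=rates, mean_temps=mean_t)
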