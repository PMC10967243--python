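"""Monotone P-spline growth curves and QMER phenology extraction.

Plot-level canopy height series are smoothed with shape-constrained
P-splines: a cubic B-spline basis with a second-order difference penalty on
the coefficients, plus a large asymmetric quadratic penalty on negative
coefficient first-differences that enforces a monotonically non-decreasing
fit (non-decreasing B-spline coefficients are sufficient for a
non-decreasing spline).  The smoothing parameter is chosen by generalized
cross-validation.

Phenology is read off the fitted elongation-rate curve with the
quarter-of-maximum-elongation-rate (QMER) rule: the start of stem elongation
(jointing, tPHstart) is the first time the rate exceeds 1/4 of its peak and
the stop (tPHstop) the last such time.  When the criterion is already met at
the first (last) grid point the event precedes (follows) the observation
window and is reported as undetermined rather than as the window edge.
Final height PH_max is the median of the largest ``top_k`` spline
predictions after tPHstop; on the default hourly grid, top_k = 24
corresponds to one day's worth of predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import BSpline

HOUR = 1.0 / 24.0


class UnfitTableError(ValueError):
    """Series has too few points for spline fitting."""


@dataclass
class SplineFit:
    knots: np.ndarray
    degree: int
    coef: np.ndarray
    lam: float
    t_min: float
    t_max: float
    resid_sd: float
    eff_df: float
    converged: bool
    monotone_tol: float = 1e-8

    def predict(self, t) -> np.ndarray:
        t = np.clip(np.asarray(t, float), self.t_min, self.t_max)
        return BSpline(self.knots, self.coef, self.degree)(t)

    def derivative(self, t) -> np.ndarray:
        t = np.clip(np.asarray(t, float), self.t_min, self.t_max)
        return BSpline(self.knots, self.coef, self.degree).derivative()(t)

    def grid(self, step: float = HOUR) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + step / 2, step)


@dataclass
class PhenologyTraits:
    tPHstart: Optional[float]
    tPHstop: Optional[float]
    PH_max: Optional[float]
    flags: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.flags


def _bspline_knots(t0: float, t1: float, n_inner: int, degree: int) -> np.ndarray:
    # uniformly extended (not clamped) knots: the difference penalty then
    # leaves polynomials up to the penalty order unshrunk everywhere
    h = (t1 - t0) / (n_inner + 1)
    return t0 + h * np.arange(-degree, n_inner + 2 + degree)


def fit_monotone_pspline(times, heights, knots_per_day: float = 1.0 / 3.0,
                         degree: int = 3, penalty_order: int = 2,
                         lam: Optional[float] = None,
                         lam_grid=None, kappa: float = 1e6,
                         max_iter: int = 50) -> SplineFit:
    """Fit a monotonically non-decreasing P-spline to one height series.

    ``knots_per_day`` controls basis density (default: one interior knot per
    ~3 days of span).  When ``lam`` is None the smoothing parameter is chosen
    from ``lam_grid`` (default log-spaced 1e-3..1e5) by GCV, with the
    monotonicity penalty active during selection.
    """
    t = np.asarray(times, float)
    y = np.asarray(heights, float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if len(np.unique(t)) < 4:
        raise UnfitTableError(f"need >= 4 distinct time points, got {len(np.unique(t))}")
    if not np.all(np.isfinite(y)):
        raise UnfitTableError("heights must be finite")
    t0, t1 = float(t[0]), float(t[-1])
    n_inner = max(int(round((t1 - t0) * knots_per_day)), 2)
    # never exceed data support: cap basis size near the number of points
    n_inner = min(n_inner, max(len(t) - degree, 2))
    knots = _bspline_knots(t0, t1, n_inner, degree)
    n_coef = len(knots) - degree - 1
    B = BSpline.design_matrix(t, knots, degree).toarray()
    D = np.diff(np.eye(n_coef), n=penalty_order, axis=0)
    D1 = np.diff(np.eye(n_coef), n=1, axis=0)
    BtB = B.T @ B
    Bty = B.T @ y
    P = D.T @ D

    def solve(lam_val):
        c = np.linalg.solve(BtB + lam_val * P + 1e-10 * np.eye(n_coef), Bty)
        converged = False
        for _ in range(max_iter):
            neg = (D1 @ c) < 0
            W = D1[neg]
            A = BtB + lam_val * P + kappa * (W.T @ W) + 1e-10 * np.eye(n_coef)
            c_new = np.linalg.solve(A, Bty)
            if np.array_equal((D1 @ c_new) < 0, neg):
                c = c_new
                converged = True
                break
            c = c_new
        # effective df from the converged system
        H = np.linalg.solve(A if max_iter else BtB + lam_val * P, BtB)
        ed = float(np.trace(H))
        resid = y - B @ c
        return c, ed, float(resid @ resid), converged

    if lam is None:
        if lam_grid is None:
            lam_grid = np.logspace(-3, 5, 13)
        best = None
        for lv in lam_grid:
            c, ed, rss, conv = solve(lv)
            denom = max(len(t) - ed, 1e-6)
            gcv = len(t) * rss / denom ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lv, c, ed, rss, conv)
        _, lam, c, ed, rss, conv = best
    else:
        c, ed, rss, conv = solve(lam)

    resid_sd = float(np.sqrt(rss / max(len(t) - ed, 1.0)))
    return SplineFit(knots=knots, degree=degree, coef=c, lam=float(lam),
                     t_min=t0, t_max=t1, resid_sd=resid_sd, eff_df=ed,
                     converged=conv)


def extract_timing_qmer(fit: SplineFit, threshold_fraction: float = 0.25,
                        grid_step: float = HOUR):
    """QMER start/stop extraction from the spline's elongation-rate curve.

    Returns ``(tPHstart, tPHstop, flags)``; an undetermined boundary is None
    with a reason code in ``flags``.
    """
    grid = fit.grid(grid_step)
    r = fit.derivative(grid)
    peak = float(r.max())
    flags = []
    if peak <= 1e-9:
        return None, None, ["no growth"]
    above = r >= threshold_fraction * peak
    idx = np.where(above)[0]
    t_start: Optional[float] = float(grid[idx[0]])
    t_stop: Optional[float] = float(grid[idx[-1]])
    if idx[0] == 0:
        t_start = None
        flags.append("tPHstart undetermined: criterion met at first observation")
    if idx[-1] == len(grid) - 1:
        t_stop = None
        flags.append("tPHstop undetermined: criterion met at last observation")
    return t_start, t_stop, flags


def extract_final_height(fit: SplineFit, tPHstop: Optional[float],
                         top_k: int = 24, grid_step: float = HOUR):
    """PH_max: median of the ``top_k`` largest spline predictions after stop.

    Returns ``(PH_max, flags)``; undetermined (None) when tPHstop is.
    """
    if tPHstop is None:
        return None, ["PH_max undetermined: tPHstop undetermined"]
    grid = fit.grid(grid_step)
    post = grid[grid > tPHstop]
    flags = []
    if len(post) == 0:
        return None, ["PH_max undetermined: no predictions after tPHstop"]
    pred = fit.predict(post)
    if len(pred) < top_k:
        flags.append(f"only {len(pred)} post-stop grid points (< {top_k})")
        top = pred
    else:
        top = np.sort(pred)[-top_k:]
    return float(np.median(top)), flags


def extract_phenology(times, heights, threshold_fraction: float = 0.25,
                      top_k: int = 24, grid_step: float = HOUR,
                      **spline_kwargs) -> PhenologyTraits:
    """Fit the monotone P-spline and extract tPHstart, tPHstop and PH_max."""
    fit = fit_monotone_pspline(times, heights, **spline_kwargs)
    t_start, t_stop, flags = extract_timing_qmer(fit, threshold_fraction,
                                                 grid_step)
    ph_max, f2 = extract_final_height(fit, t_stop, top_k, grid_step)
    return PhenologyTraits(tPHstart=t_start, tPHstop=t_stop, PH_max=ph_max,
                           flags=flags + f2)
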