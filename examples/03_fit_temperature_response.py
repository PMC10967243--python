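"""Fit the asymptotic temperature dose-response model to one plot.

Growth between sparse height measurements is explained by accumulating the
hourly rate r(T) = r_max (1 - exp(-exp(lrc)(T - T_min))) over the
elongation window; maximum likelihood recovers the parameters.
"""

from stemtherm import SimConfig, simulate_trial
from stemtherm.doseresponse import fit_asymptotic, fit_linear_slope
from stemtherm.growthcurves import extract_phenology

ds = simulate_trial(SimConfig(n_geno=10, years=(2017,), n_checks=0, seed=3))
rec = ds.design.plots.iloc[0]
hs = ds.heights[rec.plot_id]
temps = ds.temperature[rec.year]

ph = extract_phenology(hs.times, hs.heights)
window = (ph.tPHstart - 3.0, ph.tPHstop + 3.0)
fit = fit_asymptotic(hs.times, hs.heights, temps.times, temps.values,
                     window, seed=0)
lin = fit_linear_slope(hs.times, hs.heights, temps.times, temps.values, window)

truth = ds.truth.values.loc[rec.genotype]
p = fit.params
print(f"plot {rec.plot_id}: window day {window[0]:.1f}..{window[1]:.1f}")
print(f"  T_min = {p.T_min:5.2f} C     (true {truth.T_min:5.2f})")
print(f"  r_max = {p.r_max:5.3f} mm/h  (true {truth.r_max:5.3f})")
print(f"  lrc   = {p.lrc:5.2f}        (true {truth.lrc:5.2f})")
print(f"  residual sd {p.sigma*1000:.1f} mm, flags: {fit.flags or 'none'}")
print(f"  linear benchmark lm_slope = {lin.lm_slope:.4f} mm/h/C "
      f"(R^2 = {lin.r_squared:.2f})")
print("\nT_min and r_max are usually well determined from a single plot;")
print("lrc (steepness) has a flat likelihood when the true response is")
print("near-stepwise and stabilizes only through multi-year aggregation.")
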