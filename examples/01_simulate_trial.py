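"""Simulate a small multi-year wheat trial and look at what it contains.

The generator produces everything a real phenotyping campaign would: a
field design with checks, hourly weather per season, plot-level canopy
height time series, a SNP panel and the (normally unobservable) true
genotype parameters.
"""

from stemtherm import SimConfig, simulate_trial

cfg = SimConfig(n_geno=30, years=(2017, 2018), n_checks=3, seed=11)
ds = simulate_trial(cfg)

print(f"plots:           {len(ds.design.plots)}")
print(f"genotypes:       {ds.panel.n_geno} ({cfg.n_checks} checks)")
print(f"markers:         {ds.panel.n_markers} on "
      f"{ds.panel.map['chrom'].nunique()} chromosomes")
for year, ts in ds.temperature.items():
    print(f"season {year}:     {len(ts.values)} hourly temperatures, "
          f"{ts.values.min():.1f}..{ts.values.max():.1f} C")
one = next(iter(ds.heights.values()))
print(f"plot {one.plot_id}: {len(one.times)} height measurements, "
      f"final {one.heights[-1]:.3f} m")
print("\ntrue genotype parameters (first 3):")
print(ds.truth.values.head(3).round(3))
print("\nEach genotype carries true values for the base temperature T_min,")
print("maximum rate r_max, steepness lrc, and the start/stop of elongation;")
print("downstream stages are judged by how well they recover these.")
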