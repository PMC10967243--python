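# Small end-to-end run configuration for the CLI:
#   stemtherm run-all --config examples/smoke_config.yaml --out run1 --seed 7
outdir: run1
seed: 7
sim:
  n_geno: 20
  years: [2015, 2016]
  n_checks: 2
  n_chrom: 5
  snps_per_chrom: 30
cv_folds: 4
cv_repeats: 1
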