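"""Recovery and calibration benchmarks for the whole pipeline.

Each function simulates data under fixed, documented study conditions with
known ground truth, runs the corresponding estimator, and returns the
measured recovery/calibration summaries.  They are used both by the test
suite and by ``scripts/acceptance.py``; every function is deterministic
given its ``seed``.

Benchmark conditions (chosen once; see docs/methods.md):

* dose-response recovery: T_min = 4 degC, r_max = 0.8 mm/h, lrc = 3,
  elongation window day 25-90 of a 110 d season, hourly temperatures
  spanning about -2..22 degC (ramp 3->17 degC, 5 degC diurnal amplitude,
  AR(1) sd 1 degC), measurements every 3 d, 5 mm measurement noise;
* genetic benchmarks: 300-genotype founder-mosaic panels on 21 chromosomes
  (trial defaults) for GBLUP and genetic correlations, an unstructured
  300 x 2000 panel for GWAS calibration and power.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from .doseresponse import fit_asymptotic
from .growthcurves import extract_final_height, extract_timing_qmer, fit_monotone_pspline
from .lmm import RandomTerm, build_design, reml_lmm
from .quantgen import (bonferroni_threshold, gblup_cv, genetic_correlation,
                       gwas_mlm, ibs_kinship)
from .simdata import (gen_genetic_values, gen_marker_panel,
                      gen_temperature_series, simulate_plot_height)
from .stagewise import stage2_adjust, stage3_combine


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------


def bonferroni_check(n_markers: int = 9147, alpha: float = 0.05) -> float:
    """Genome-wide Bonferroni threshold on the -log10 p scale."""
    return bonferroni_threshold(n_markers, alpha)


def dose_response_recovery(seed: int = 0, n_plots: int = 100) -> Dict[str, float]:
    """Median recovery errors of the asymptotic-model ML fit.

    ``n_plots`` plots simulated with T_min = 4, r_max = 0.8, lrc = 3,
    5 mm noise, 3 d sampling, temperatures spanning about -2..22 degC.
    Returns median |T_min error| (degC), median relative r_max error (%),
    and median |lrc error|.
    """
    truth = pd.Series({"T_min": 4.0, "r_max": 0.8, "lrc": 3.0,
                       "start": 25.0, "stop": 90.0})
    sched = np.arange(20.0, 95.0, 3.0)
    errs = []
    for k in range(n_plots):
        s = _sub_seed(seed, k)
        temps = gen_temperature_series(110, (3.0, 17.0), 5.0, 1.0, 0.7, seed=s)
        hs = simulate_plot_height(truth, temps, sched, 0.0, 0.005,
                                  H0=0.15, seed=s + 1)
        fit = fit_asymptotic(hs.times, hs.heights, temps.times, temps.values,
                             (25.0, 90.0), n_starts=8, seed=s)
        if fit.status != "ok":
            continue
        errs.append((abs(fit.params.T_min - 4.0),
                     abs(fit.params.r_max - 0.8) / 0.8,
                     abs(fit.params.lrc - 3.0)))
    e = np.array(errs)
    return {"tmin_median_abs_error_c": float(np.median(e[:, 0])),
            "rmax_median_rel_error_pct": float(np.median(e[:, 1]) * 100.0),
            "lrc_median_abs_error": float(np.median(e[:, 2])),
            "n_fits": len(errs)}


def qmer_logistic_check() -> Dict[str, float]:
    """QMER timing and PH_max on a noise-free logistic growth curve.

    Logistic K = 1 m, k = 0.2 /d, midpoint 50 d, sampled daily on [0, 100];
    the quarter-of-peak-rate times are analytically 50 -+ ln(7 + 4 sqrt(3))/k
    = 36.83 and 63.17 d.
    """
    t = np.arange(0.0, 101.0)
    y = 1.0 / (1.0 + np.exp(-0.2 * (t - 50.0)))
    fit = fit_monotone_pspline(t, y)
    t_start, t_stop, _ = extract_timing_qmer(fit)
    ph_max, _ = extract_final_height(fit, t_stop)
    return {"tphstart_d": float(t_start), "tphstop_d": float(t_stop),
            "phmax_m": float(ph_max)}


def twostage_equivalence(seed: int = 0, n_geno: int = 200,
                         n_rep: int = 2, n_years: int = 2) -> Dict[str, float]:
    """Max |two-stage BLUE - one-stage BLUE| on a balanced complete trial.

    The one-stage oracle fits the combined model (genotype and year fixed,
    genotype-by-year cell random) directly to plot data; the two-stage path
    computes per-year adjusted means and combines them unweighted.
    """
    rng = np.random.default_rng(seed)
    g_eff = rng.standard_normal(n_geno)
    rows = []
    for j in range(n_years):
        year = str(2015 + j)
        y_eff = rng.standard_normal() * 0.5
        gy = rng.standard_normal(n_geno) * 0.3
        for _rep in range(n_rep):
            e = rng.standard_normal(n_geno) * 0.5
            for i in range(n_geno):
                rows.append((year, f"G{i:04d}",
                             10.0 + y_eff + g_eff[i] + gy[i] + e[i]))
    df = pd.DataFrame(rows, columns=["year", "genotype", "value"])
    df["gy_cell"] = df["genotype"] + "_" + df["year"]

    s2s = [stage2_adjust(sub, year, trait="value", spatial=False)
           for year, sub in df.groupby("year")]
    s3 = stage3_combine(s2s, mode="BLUE", use_weights="off")

    X, names = build_design(df, fixed=["year"], cell_means="genotype")
    one = reml_lmm(df, "value", X, names,
                   random=[RandomTerm("gy", factor="gy_cell")])
    beta = one.beta.to_numpy()
    g_idx = [i for i, nm in enumerate(names) if nm.startswith("genotype[")]
    y_idx = [i for i, nm in enumerate(names) if nm.startswith("year[")]
    vals = pd.Series(beta[g_idx] + beta[y_idx].sum() / n_years,
                     index=[names[i][len("genotype["):-1] for i in g_idx])
    diff = (s3.genotype_values - vals[s3.genotype_values.index]).abs().max()
    return {"max_abs_diff": float(diff), "n_geno": n_geno}


def _kinship_panel(n_geno: int, seed: int, snps_per_chrom: int = 100):
    panel = gen_marker_panel(n_geno, 21, snps_per_chrom, (0.05, 0.5),
                             n_subpop=3, fst=0.1, seed=seed)
    return panel, ibs_kinship(panel)


def _simulate_plot_trait(kin_chol, genotype_ids, h2: float, n_years: int,
                         n_rep: int, rng, var_gy: float = 0.3,
                         var_e: float = 0.7) -> pd.DataFrame:
    """Plot-level trait with kinship-structured genetic values.

    Var(genotype) = h2; the non-genetic part (1 - h2) splits into
    genotype-year interaction and plot error in ratio var_gy : var_e.
    """
    n = len(genotype_ids)
    g = kin_chol @ rng.standard_normal(n) * np.sqrt(h2)
    rows = []
    for j in range(n_years):
        year = 2015 + j
        y_eff = rng.standard_normal() * 0.5
        gy = rng.standard_normal(n) * np.sqrt(var_gy * (1 - h2))
        for _rep in range(n_rep):
            e = rng.standard_normal(n) * np.sqrt(var_e * (1 - h2))
            for i, gid in enumerate(genotype_ids):
                rows.append((year, gid, 10.0 + y_eff + g[i] + gy[i] + e[i]))
    return pd.DataFrame(rows, columns=["year", "genotype", "value"])


def heritability_monotonicity(seed: int = 0, n_seeds: int = 10,
                              n_geno: int = 200,
                              h2_levels=(0.0, 0.3, 0.6, 0.9)) -> Dict[str, float]:
    """Mean H2_delta_blup per simulated h2 level (kinship BLUP, stage 2+3)."""
    panel, kin = _kinship_panel(n_geno, _sub_seed(seed, 999))
    chol = np.linalg.cholesky(kin.matrix + 1e-8 * np.eye(n_geno))
    out = {}
    for h2 in h2_levels:
        vals = []
        for k in range(n_seeds):
            rng = np.random.default_rng(_sub_seed(seed, int(h2 * 100) * 100 + k))
            df = _simulate_plot_trait(chol, panel.genotype_ids, h2, 4, 2, rng)
            s2s = [stage2_adjust(sub, yr, trait="value", spatial=False)
                   for yr, sub in df.groupby("year")]
            s3 = stage3_combine(s2s, mode="BLUP", kinship=kin.matrix,
                                kin_ids=kin.genotype_ids, use_weights="off")
            vals.append(s3.H2_delta_blup)
        out[f"H2_at_h2_{h2:g}"] = float(np.mean(vals))
    return out


def gblup_accuracy_bounds(seed: int = 0, n_geno: int = 300, k: int = 10,
                          repeats: int = 10) -> Dict[str, float]:
    """Mean 10x10-fold GBLUP CV accuracy for h2 = 0 and h2 = 0.9 traits.

    Traits have 40 QTL drawn from the trial-default founder-mosaic panel.
    """
    panel = gen_marker_panel(n_geno, 21, 436, (0.05, 0.5), n_subpop=3,
                             fst=0.1, founders_per_subpop=5,
                             seed=_sub_seed(seed, 1))
    kin = ibs_kinship(panel)
    out = {}
    for h2, tag in [(0.0, "h2_0"), (0.9, "h2_09")]:
        truth = gen_genetic_values(panel, ["t"], {"t": h2}, np.eye(1),
                                   {"t": 0.0}, {"t": 1.0}, n_qtl=40,
                                   seed=_sub_seed(seed, 2 + int(h2 * 10)))
        cv = gblup_cv(truth.values["t"], kin, k=k, repeats=repeats,
                      seed=_sub_seed(seed, 7))
        out[f"gblup_r_{tag}"] = float(cv.mean_r)
        out[f"gblup_r_var_{tag}"] = float(cv.var_r)
    return out


def genetic_correlation_recovery(seed: int = 0, n_seeds: int = 20,
                                 n_geno: int = 300, n_years: int = 4,
                                 h2: float = 0.7) -> Dict[str, float]:
    """Median bivariate-REML genetic-correlation estimate at rho_g = 0, 0.8.

    Genotype effects are drawn model-consistently from N(0, Sigma_g x K);
    the non-genetic cell variance is (1 - h2)/h2 of the genetic variance.
    """
    panel, kin = _kinship_panel(n_geno, _sub_seed(seed, 5))
    chol = np.linalg.cholesky(kin.matrix + 1e-8 * np.eye(n_geno))
    out = {}
    for rho in (0.0, 0.8):
        S = np.array([[1.0, rho], [rho, 1.0]])
        cS = np.linalg.cholesky(S + 1e-10 * np.eye(2))
        ests = []
        for kdx in range(n_seeds):
            rng = np.random.default_rng(_sub_seed(seed, 10000 + int(rho * 10) * 100 + kdx))
            g = chol @ rng.standard_normal((n_geno, 2)) @ cS.T
            sig_e = np.sqrt((1.0 / h2 - 1.0) * g.var(axis=0).mean())
            rows = []
            for j in range(n_years):
                y_eff = rng.standard_normal(2) * 0.5
                noise = rng.standard_normal((n_geno, 2)) * sig_e
                for i, gid in enumerate(panel.genotype_ids):
                    rows.append((gid, 2015 + j, "a", g[i, 0] + y_eff[0] + noise[i, 0]))
                    rows.append((gid, 2015 + j, "b", g[i, 1] + y_eff[1] + noise[i, 1]))
            df = pd.DataFrame(rows, columns=["genotype", "year", "trait", "blue"])
            gc = genetic_correlation(df, "a", "b", kin)
            if gc.correlation is not None:
                ests.append(gc.correlation)
        out[f"rg_median_rho_{rho:g}"] = float(np.median(ests))
    return out


def gwas_calibration_and_power(seed: int = 0, n_geno: int = 300,
                               n_markers: int = 2000,
                               n_power_seeds: int = 20) -> Dict[str, float]:
    """Type-I calibration under a polygenic null and power for a 20% QTL.

    Null: phenotype = polygenic (h2 = 0.5, all markers) + noise, no major
    QTL; reported is the fraction of markers with p < 0.05.  Power: one
    planted QTL explaining 20% of phenotypic variance over a 30% polygenic
    background; reported is the fraction of seeds in which the planted
    marker attains the genome-wide minimum p.
    """
    panel = gen_marker_panel(n_geno, 10, n_markers // 10, (0.05, 0.5),
                             n_subpop=1, fst=0.0, founders_per_subpop=None,
                             seed=_sub_seed(seed, 21))
    kin = ibs_kinship(panel)
    M = panel.imputed()
    Mc = M - M.mean(axis=0)
    m = Mc.shape[1]

    rng = np.random.default_rng(_sub_seed(seed, 22))
    u = Mc @ rng.standard_normal(m)
    u = u / u.std()
    y = np.sqrt(0.5) * u + np.sqrt(0.5) * rng.standard_normal(n_geno)
    res = gwas_mlm(pd.Series(y, index=panel.genotype_ids), panel, kin, n_pc=3)
    type1 = float((res.table["p"] < 0.05).mean())

    hits = 0
    for kdx in range(n_power_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 1000 + kdx))
        q = int(rng.integers(0, m))
        x = Mc[:, q]
        while x.std() < 1e-9:
            q = int(rng.integers(0, m))
            x = Mc[:, q]
        qtl = x / x.std() * np.sqrt(0.2)
        bg = Mc @ rng.standard_normal(m)
        bg = bg / bg.std() * np.sqrt(0.3)
        yq = qtl + bg + rng.standard_normal(n_geno) * np.sqrt(0.5)
        r = gwas_mlm(pd.Series(yq, index=panel.genotype_ids), panel, kin,
                     n_pc=3)
        hits += int(r.table["p"].idxmin() == q)
    return {"gwas_type1_frac": type1,
            "gwas_power_top_marker_frac": hits / n_power_seeds,
            "bonferroni_neglog10p_2000": bonferroni_threshold(m)}
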