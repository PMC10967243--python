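"""Synthetic multi-year wheat field trials with known ground truth.

Every downstream stage of the package (spline phenology extraction,
dose-response fitting, stage-wise mixed models, genomic analyses) is tested
against data from this module, because the field data the method was
developed on are not publicly deposited.  The generator emulates:

* a structured SNP panel (several hundred genotypes, 21 chromosomes,
  ~9000 markers) with block/decay linkage disequilibrium and optional
  subpopulation divergence,
* per-genotype true temperature-response parameters (T_min, r_max, lrc) and
  phenology (start/stop of stem elongation) built from additive marker
  effects with chosen heritabilities and genetic correlations,
* hourly air-temperature seasons (seasonal ramp + diurnal cycle + AR(1)
  noise),
* two-replicate augmented field designs with systematic checks in a 3x3
  block arrangement, over multiple years,
* plot-level canopy height time series produced by the same hourly
  accumulation model the fitting code assumes, plus spatial field gradients
  and measurement noise.

Default parameter values mirror the trial system the package targets:
about 345 genotypes replicated twice per year over four seasons, height
measurements every ~3 days, and a marker panel of 21 x 436 SNPs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .doseresponse import DoseResponseParams, accumulate_heights

COUNTRY_GROUPS = ["AT/CZ", "PL", "DE", "CH", "SE/DK", "FR", "UK"]
ERA_GROUPS = ["(1970,1990]", "(1990,1995]", "(1995,2000]",
              "(2000,2005]", "(2005,2018]"]
TRAIT_NAMES = ["T_min", "r_max", "lrc", "start", "stop"]


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MarkerPanel:
    """Allele-dosage matrix with a genetic map.

    ``genotypes`` is (n_geno x n_markers) with entries in {0, 1, 2} or NaN
    for missing; ``map`` has one row per marker column with ``chrom`` and
    ``pos`` (bp), sorted by (chrom, pos).
    """

    genotype_ids: List[str]
    genotypes: np.ndarray
    map: pd.DataFrame
    subpop: Optional[np.ndarray] = None

    def __post_init__(self):
        g = self.genotypes
        valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or NaN")
        if len(self.map) != g.shape[1]:
            raise ValueError("one map row per marker column required")

    @property
    def n_geno(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing values replaced by the marker mean."""
        g = self.genotypes.copy()
        means = np.nanmean(g, axis=0)
        nan_r, nan_c = np.where(np.isnan(g))
        g[nan_r, nan_c] = means[nan_c]
        return g

    def maf(self) -> np.ndarray:
        p = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class TrueGenotypeParams:
    """Per-genotype ground truth for the simulated panel."""

    genotype_ids: List[str]
    values: pd.DataFrame          # realized genotype-level parameter values
    genetic_values: pd.DataFrame  # purely additive component of `values`
    h2: Dict[str, float]
    sigma_g: pd.DataFrame         # generating genetic correlation matrix

    def __post_init__(self):
        if "r_max" in self.values and (self.values["r_max"] <= 0).any():
            raise ValueError("r_max_true must be positive")
        if {"start", "stop"} <= set(self.values.columns) and (
                self.values["stop"] <= self.values["start"]).any():
            raise ValueError("stop_true must exceed start_true")


@dataclass
class TemperatureSeries:
    """Hourly air temperature for one season.

    ``times`` are hour start times in fractional days since sowing with
    constant 1 h spacing; ``values`` in degC.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1.0 / 24.0, atol=1e-9):
            raise ValueError("temperature series must be hourly")
        if np.isnan(self.values).any():
            raise ValueError("temperature series contains missing values")


@dataclass
class FieldDesign:
    """Plot layout plus genotype metadata."""

    plots: pd.DataFrame     # plot_id, year, rep, row, range, genotype, is_check
    genotype_meta: pd.DataFrame  # genotype, country, era

    def __post_init__(self):
        dup = self.plots.duplicated(subset=["year", "row", "range"])
        if dup.any():
            raise ValueError("(year, row, range) must be unique")


@dataclass
class HeightSeries:
    """One plot's irregular canopy-height measurements."""

    plot_id: str
    times: np.ndarray     # days since sowing, strictly increasing
    heights: np.ndarray   # meters, >= 0
    platform: str = "sim"

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.heights < 0):
            raise ValueError("heights must be non-negative")


@dataclass
class TrialDataset:
    design: FieldDesign
    temperature: Dict[int, TemperatureSeries]
    heights: Dict[str, HeightSeries]
    panel: MarkerPanel
    truth: TrueGenotypeParams
    config: "SimConfig"
    seed: int

    def heights_frame(self) -> pd.DataFrame:
        recs = []
        for hs in self.heights.values():
            for t, h in zip(hs.times, hs.heights):
                recs.append((hs.plot_id, t, h))
        return pd.DataFrame(recs, columns=["plot_id", "day", "height_m"])

    def temperature_frame(self) -> pd.DataFrame:
        recs = []
        for year, ts in self.temperature.items():
            recs.append(pd.DataFrame({"year": year, "day_hour": ts.times,
                                      "temp_c": ts.values}))
        return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# marker panel


def gen_marker_panel(n_geno: int, n_chrom: int = 21, snps_per_chrom: int = 436,
                     maf_range: Tuple[float, float] = (0.05, 0.5),
                     n_subpop: int = 1, fst: float = 0.0,
                     ld_corr_bp: float = 5e6, chrom_length_bp: float = 7e8,
                     founders_per_subpop: Optional[int] = None,
                     crossovers_per_chrom: float = 1.0,
                     missing_rate: float = 0.0, genotype_ids=None,
                     seed: int = 0) -> MarkerPanel:
    """Simulate a structured SNP dosage panel with decaying local LD.

    Founder haplotypes are thresholded latent Gaussian AR(1) processes along
    each chromosome (correlation exp(-d/ld_corr_bp) between markers d bp
    apart), which yields blockwise LD that decays with map distance.
    Subpopulation allele frequencies follow a Balding-Nichols model with
    divergence ``fst``.  Each individual's two haplotypes are recombinant
    mosaics of the subpopulation's founder pool (``founders_per_subpop``
    founders, on average ``crossovers_per_chrom`` switches per chromosome),
    emulating the family relatedness and long-range LD of a closed breeding
    pool; set ``founders_per_subpop=None`` for unrelated individuals.
    """
    if n_geno < 2:
        raise ConfigurationError("need at least 2 genotypes")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must lie within (0, 0.5]")
    if n_chrom < 1 or snps_per_chrom < 1:
        raise ConfigurationError("need at least one marker")
    rng = np.random.default_rng(seed)

    if genotype_ids is None:
        genotype_ids = [f"G{i + 1:04d}" for i in range(n_geno)]
    n_sub = max(n_subpop, 1)
    subpop = np.arange(n_geno) % n_sub

    chrom_names = [f"chr{c + 1:02d}" for c in range(n_chrom)]
    maps = []
    dosage_blocks = []
    mosaic = founders_per_subpop is not None
    n_hap_draw = (n_sub * founders_per_subpop if mosaic else 2 * n_geno)
    hap_owner = (np.repeat(np.arange(n_sub), founders_per_subpop) if mosaic
                 else np.repeat(subpop, 2))
    for c, chrom in enumerate(chrom_names):
        pos = np.sort(rng.choice(int(chrom_length_bp), size=snps_per_chrom,
                                 replace=False)) + 1
        p_anc = rng.uniform(lo, hi, size=snps_per_chrom)
        # per-subpopulation frequencies (Balding-Nichols)
        if n_sub > 1 and fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_sub = np.clip(rng.beta(a[None, :].repeat(n_sub, 0),
                                     b[None, :].repeat(n_sub, 0)),
                            0.01, 0.99)
        else:
            p_sub = p_anc[None, :].repeat(n_sub, 0)
        # latent AR(1) along the chromosome for each base haplotype
        rho = np.exp(-np.diff(pos) / ld_corr_bp)
        z = np.empty((n_hap_draw, snps_per_chrom))
        z[:, 0] = rng.standard_normal(n_hap_draw)
        eps = rng.standard_normal((n_hap_draw, snps_per_chrom - 1))
        for m in range(1, snps_per_chrom):
            r = rho[m - 1]
            z[:, m] = r * z[:, m - 1] + np.sqrt(1.0 - r * r) * eps[:, m - 1]
        thr = norm.ppf(p_sub)                        # (n_sub, M)
        base = (z < thr[hap_owner, :]).astype(float)
        if mosaic:
            alleles = np.empty((2 * n_geno, snps_per_chrom))
            p_switch = min(crossovers_per_chrom / max(snps_per_chrom - 1, 1), 1.0)
            for h in range(2 * n_geno):
                sp = subpop[h // 2]
                pool = np.where(hap_owner == sp)[0]
                picks = rng.integers(0, len(pool),
                                     size=snps_per_chrom)
                switch = rng.random(snps_per_chrom) < p_switch
                switch[0] = True
                path = pool[picks[np.maximum.accumulate(
                    np.where(switch, np.arange(snps_per_chrom), -1))]]
                alleles[h] = base[path, np.arange(snps_per_chrom)]
        else:
            alleles = base
        dos = alleles[0::2] + alleles[1::2]
        dosage_blocks.append(dos)
        maps.append(pd.DataFrame({"chrom": chrom, "pos": pos}))

    genotypes = np.concatenate(dosage_blocks, axis=1)
    if missing_rate > 0:
        miss = rng.random(genotypes.shape) < missing_rate
        genotypes[miss] = np.nan
    map_df = pd.concat(maps, ignore_index=True)
    map_df["marker"] = [f"{r.chrom}_{r.pos}" for r in map_df.itertuples()]
    return MarkerPanel(genotype_ids=list(genotype_ids), genotypes=genotypes,
                       map=map_df, subpop=subpop)


# ---------------------------------------------------------------------------
# genetic values


def _check_corr(sigma_g: np.ndarray):
    s = np.asarray(sigma_g, float)
    if not np.allclose(s, s.T, atol=1e-10):
        raise ConfigurationError("sigma_g must be symmetric")
    if not np.allclose(np.diag(s), 1.0, atol=1e-8):
        raise ConfigurationError("sigma_g must have unit diagonal")
    w = np.linalg.eigvalsh(s)
    if w.min() < -1e-8:
        raise ConfigurationError("sigma_g must be positive semi-definite")
    return s


def gen_genetic_values(panel: MarkerPanel, trait_names: Sequence[str],
                       h2: Dict[str, float], sigma_g,
                       means: Dict[str, float], scales: Dict[str, float],
                       n_qtl: int = 40, seed: int = 0,
                       min_phase_gap: float = 8.0) -> TrueGenotypeParams:
    """Draw per-genotype true parameter values from additive marker effects.

    Each trait's additive genetic value is u = M a with ``n_qtl`` shared QTL
    and effect vectors drawn with cross-trait covariance ``sigma_g``; a
    non-genetic genotype-level deviation is added so that the genotype-mean
    heritability matches ``h2``.  Values are returned on natural scales via
    ``means``/``scales``.
    """
    traits = list(trait_names)
    S = _check_corr(sigma_g)
    if S.shape[0] != len(traits):
        raise ConfigurationError("sigma_g dimension must match trait count")
    if n_qtl > panel.n_markers:
        raise ConfigurationError("n_qtl exceeds marker count")
    rng = np.random.default_rng(seed)
    M = panel.imputed()
    M = M - M.mean(axis=0)
    qtl = rng.choice(panel.n_markers, size=n_qtl, replace=False)
    # effect vectors with cross-trait covariance sigma_g at each QTL
    L = np.linalg.cholesky(S + 1e-10 * np.eye(len(traits)))
    A = rng.standard_normal((n_qtl, len(traits))) @ L.T
    u = M[:, qtl] @ A
    sd = u.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    u_std = u / sd

    n = panel.n_geno
    vals = {}
    gvals = {}
    for t_idx, t in enumerate(traits):
        h = float(h2[t])
        if not 0.0 <= h <= 1.0:
            raise ConfigurationError(f"h2[{t}] must be in [0, 1]")
        e = rng.standard_normal(n)
        g_part = np.sqrt(h) * u_std[:, t_idx]
        val = means[t] + scales[t] * (g_part + np.sqrt(1.0 - h) * e)
        vals[t] = val
        gvals[t] = means[t] + scales[t] * g_part
    values = pd.DataFrame(vals, index=panel.genotype_ids)
    genetic = pd.DataFrame(gvals, index=panel.genotype_ids)

    if "r_max" in values:
        values["r_max"] = values["r_max"].clip(lower=0.05)
    if {"start", "stop"} <= set(values.columns):
        bad = values["stop"] < values["start"] + min_phase_gap
        values.loc[bad, "stop"] = values.loc[bad, "start"] + min_phase_gap
    return TrueGenotypeParams(
        genotype_ids=list(panel.genotype_ids), values=values,
        genetic_values=genetic, h2=dict(h2),
        sigma_g=pd.DataFrame(S, index=traits, columns=traits))


# ---------------------------------------------------------------------------
# temperature


def gen_temperature_series(season_length: int, mean_curve=(4.0, 18.0),
                           diurnal_amplitude: float = 5.0,
                           noise_sd: float = 1.5, noise_ar: float = 0.7,
                           peak_hour: float = 14.0,
                           seed: int = 0) -> TemperatureSeries:
    """Hourly temperature: seasonal linear ramp + diurnal cosine + AR(1) noise."""
    if season_length < 30:
        raise ConfigurationError("season_length must be >= 30 days")
    if diurnal_amplitude < 0 or noise_sd < 0:
        raise ConfigurationError("amplitude and noise sd must be non-negative")
    n = 24 * int(season_length)
    hours = np.arange(n)
    times = hours / 24.0
    t0, t1 = mean_curve
    ramp = t0 + (t1 - t0) * times / season_length
    diurnal = diurnal_amplitude * np.cos(2 * np.pi * (hours % 24 - peak_hour) / 24.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = np.empty(n)
        x[0] = rng.standard_normal() * noise_sd
        innov_sd = noise_sd * np.sqrt(max(1.0 - noise_ar ** 2, 0.0))
        eps = rng.standard_normal(n - 1) * innov_sd
        for h in range(1, n):
            x[h] = noise_ar * x[h - 1] + eps[h - 1]
    else:
        x = np.zeros(n)
    return TemperatureSeries(times=times, values=ramp + diurnal + x)


# ---------------------------------------------------------------------------
# plot height forward model


def simulate_plot_height(truth_row, temps: TemperatureSeries, schedule,
                         spatial_offset: float = 0.0, noise_sd: float = 0.0,
                         H0: float = 0.15, plot_id: str = "plot",
                         seed: int = 0) -> HeightSeries:
    """Forward-simulate one plot's height series.

    ``truth_row`` must carry T_min, r_max, lrc, start, stop (natural units).
    Latent height accumulates the hourly dose-response rate inside the true
    elongation window; the observation adds the plot's spatial offset and
    i.i.d. Gaussian noise, truncated at zero.
    """
    schedule = np.asarray(schedule, float)
    if schedule.min() < temps.times[0] - 1e-9 or schedule.max() > temps.times[-1] + 1.0 / 24.0:
        raise ValueError(
            f"schedule spans [{schedule.min():.2f}, {schedule.max():.2f}] d but "
            f"temperatures cover [{temps.times[0]:.2f}, {temps.times[-1]:.2f}] d")
    start, stop = float(truth_row["start"]), float(truth_row["stop"])
    if stop <= start:
        raise ValueError("stop_true must exceed start_true")
    params = DoseResponseParams(T_min=float(truth_row["T_min"]),
                                r_max=float(truth_row["r_max"]),
                                lrc=float(truth_row["lrc"]), H0=H0)
    latent = accumulate_heights(params, temps.times, temps.values,
                                (start, stop), schedule)
    rng = np.random.default_rng(seed)
    obs = latent + spatial_offset
    if noise_sd > 0:
        obs = obs + rng.standard_normal(len(schedule)) * noise_sd
    obs = np.clip(obs, 0.0, None)
    return HeightSeries(plot_id=plot_id, times=schedule, heights=obs)


# ---------------------------------------------------------------------------
# field design


def gen_field_design(n_geno: int, n_rep: int = 2,
                     years: Sequence[int] = (2015, 2016, 2017, 2018),
                     n_checks: int = 3, n_ranges: int = 18,
                     genotype_ids=None, seed: int = 0,
                     max_rows_per_lot: int = 1000) -> FieldDesign:
    """Randomized augmented design: each genotype once per replication per
    year, checks recurring systematically in a 3x3 block arrangement."""
    rng = np.random.default_rng(seed)
    if genotype_ids is None:
        genotype_ids = [f"G{i + 1:04d}" for i in range(n_geno)]
    genotype_ids = list(genotype_ids)
    check_ids = [f"CHK{j + 1}" for j in range(n_checks)]

    records = []
    for year in years:
        for rep in range(1, n_rep + 1):
            order = list(rng.permutation(genotype_ids))
            row_offset = (rep - 1) * max_rows_per_lot
            row, rng_pos = 1, 1
            k_check = 0
            while order:
                is_check_slot = n_checks > 0 and (row % 3 == 2 and rng_pos % 3 == 2)
                if is_check_slot:
                    geno = check_ids[k_check % n_checks]
                    k_check += 1
                    is_check = True
                else:
                    geno = order.pop()
                    is_check = False
                records.append((f"Y{year}_L{rep}_{row:03d}_{rng_pos:02d}", year,
                                rep, row + row_offset, rng_pos, geno, is_check))
                rng_pos += 1
                if rng_pos > n_ranges:
                    rng_pos = 1
                    row += 1
                    if row > max_rows_per_lot:
                        raise ConfigurationError("grid too small for all plots")
    plots = pd.DataFrame(records, columns=["plot_id", "year", "rep", "row",
                                           "range", "genotype", "is_check"])
    all_ids = genotype_ids + check_ids
    meta = pd.DataFrame({
        "genotype": all_ids,
        "country": rng.choice(COUNTRY_GROUPS, size=len(all_ids),
                              p=[0.10, 0.08, 0.25, 0.15, 0.10, 0.22, 0.10]),
        "era": rng.choice(ERA_GROUPS, size=len(all_ids),
                          p=[0.10, 0.25, 0.30, 0.25, 0.10]),
    })
    return FieldDesign(plots=plots, genotype_meta=meta)


# ---------------------------------------------------------------------------
# full trial


def _default_sigma_g() -> pd.DataFrame:
    traits = TRAIT_NAMES
    S = np.array([
        # T_min  r_max   lrc   start   stop
        [1.00,  0.50,  0.30,  -0.20, -0.40],   # T_min
        [0.50,  1.00,  0.50,  -0.10,  0.40],   # r_max
        [0.30,  0.50,  1.00,  -0.30, -0.30],   # lrc
        [-0.20, -0.10, -0.30,  1.00,  0.50],   # start
        [-0.40,  0.40, -0.30,  0.50,  1.00],   # stop
    ])
    w, V = np.linalg.eigh(S)
    if w.min() < 1e-8:
        S = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
    return pd.DataFrame(S, index=traits, columns=traits)


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_trial`.

    Defaults describe the trial system the package emulates: ~345 genotypes,
    2 replicates, 4 years, hourly temperatures over a 110 d spring season,
    measurements every ~3 d, 5 mm measurement noise, and modest spatial
    gradients.
    """

    n_geno: int = 345
    n_rep: int = 2
    years: Tuple[int, ...] = (2015, 2016, 2017, 2018)
    n_checks: int = 3
    n_ranges: int = 18
    # markers
    n_chrom: int = 21
    snps_per_chrom: int = 436
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_subpop: int = 3
    fst: float = 0.1
    ld_corr_bp: float = 5e6
    founders_per_subpop: Optional[int] = 5
    crossovers_per_chrom: float = 1.0
    # genetics of the truth
    trait_means: Dict[str, float] = dc_field(default_factory=lambda: {
        "T_min": 5.5, "r_max": 0.8, "lrc": 3.0, "start": 35.0, "stop": 80.0})
    trait_scales: Dict[str, float] = dc_field(default_factory=lambda: {
        "T_min": 0.5, "r_max": 0.10, "lrc": 0.35, "start": 2.5, "stop": 2.5})
    h2: Dict[str, float] = dc_field(default_factory=lambda: {
        "T_min": 0.3, "r_max": 0.85, "lrc": 0.6, "start": 0.8, "stop": 0.85})
    sigma_g: Optional[pd.DataFrame] = None
    n_qtl: int = 40
    # season / temperature
    season_length: int = 110
    ramp_by_year: Optional[Dict[int, Tuple[float, float]]] = None
    diurnal_amplitude: float = 5.0
    temp_noise_sd: float = 1.5
    temp_noise_ar: float = 0.7
    # measurements
    schedule_step: float = 3.0
    schedule_jitter: float = 1.0
    schedule_start: float = 10.0
    schedule_end: float = 105.0
    noise_sd: float = 0.005      # m
    H0: float = 0.15             # m
    # spatial truth (m)
    spatial_row_sd: float = 0.01
    spatial_range_sd: float = 0.01
    spatial_surface_amp: float = 0.01
    # year effects on phenology truth (days, sd)
    year_shift_sd: float = 2.0
    seed: int = 0


def simulate_trial(config: SimConfig = None, **overrides) -> TrialDataset:
    """Generate a complete trial dataset with retained ground truth."""
    if config is None:
        config = SimConfig()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(8)

    design = gen_field_design(cfg.n_geno, cfg.n_rep, cfg.years, cfg.n_checks,
                              cfg.n_ranges, seed=int(seeds[0]))
    all_ids = list(design.genotype_meta["genotype"])
    panel = gen_marker_panel(len(all_ids), cfg.n_chrom, cfg.snps_per_chrom,
                             cfg.maf_range, cfg.n_subpop, cfg.fst,
                             cfg.ld_corr_bp,
                             founders_per_subpop=cfg.founders_per_subpop,
                             crossovers_per_chrom=cfg.crossovers_per_chrom,
                             genotype_ids=all_ids, seed=int(seeds[1]))
    sigma_g = cfg.sigma_g if cfg.sigma_g is not None else _default_sigma_g()
    truth = gen_genetic_values(panel, TRAIT_NAMES, cfg.h2, sigma_g,
                               cfg.trait_means, cfg.trait_scales,
                               n_qtl=min(cfg.n_qtl, panel.n_markers),
                               seed=int(seeds[2]))

    rng = np.random.default_rng(int(seeds[3]))
    ramps = cfg.ramp_by_year or {}
    temperature = {}
    year_shift = {}
    for k, year in enumerate(cfg.years):
        ramp = ramps.get(year, (4.0 + rng.uniform(-1.5, 1.5),
                                18.0 + rng.uniform(-2.0, 3.0)))
        temperature[year] = gen_temperature_series(
            cfg.season_length, ramp, cfg.diurnal_amplitude, cfg.temp_noise_sd,
            cfg.temp_noise_ar, seed=int(seeds[4]) + k)
        year_shift[year] = (rng.standard_normal() * cfg.year_shift_sd
                            if cfg.year_shift_sd > 0 else 0.0)

    # per-year measurement schedules
    schedules = {}
    for year in cfg.years:
        base = np.arange(cfg.schedule_start, cfg.schedule_end, cfg.schedule_step)
        jit = (rng.uniform(-cfg.schedule_jitter, cfg.schedule_jitter, len(base))
               if cfg.schedule_jitter > 0 else 0.0)
        sched = np.clip(np.sort(base + jit), 0.0,
                        cfg.season_length - 1.0 / 24.0)
        schedules[year] = np.unique(np.round(sched * 24) / 24.0)

    # spatial truth per year: row + range effects + smooth cosine surface
    plots = design.plots
    spatial = {}
    for year in cfg.years:
        sub = plots[plots["year"] == year]
        rows = np.unique(sub["row"])
        rngs = np.unique(sub["range"])
        r_eff = dict(zip(rows, rng.standard_normal(len(rows)) * cfg.spatial_row_sd))
        c_eff = dict(zip(rngs, rng.standard_normal(len(rngs)) * cfg.spatial_range_sd))
        phase = rng.uniform(0, 2 * np.pi, 2)
        for rec in sub.itertuples():
            surf = cfg.spatial_surface_amp * np.cos(
                2 * np.pi * rec.row / 20.0 + phase[0]) * np.cos(
                2 * np.pi * rec.range / 12.0 + phase[1])
            spatial[rec.plot_id] = r_eff[rec.row] + c_eff[rec.range] + surf

    heights = {}
    noise_seeds = np.random.SeedSequence(int(seeds[5])).generate_state(len(plots))
    vals = truth.values
    for i, rec in enumerate(plots.itertuples()):
        tr = vals.loc[rec.genotype].copy()
        tr["start"] = tr["start"] + year_shift[rec.year]
        tr["stop"] = tr["stop"] + year_shift[rec.year]
        heights[rec.plot_id] = simulate_plot_height(
            tr, temperature[rec.year], schedules[rec.year],
            spatial_offset=spatial[rec.plot_id], noise_sd=cfg.noise_sd,
            H0=cfg.H0, plot_id=rec.plot_id, seed=int(noise_seeds[i]))

    return TrialDataset(design=design, temperature=temperature,
                        heights=heights, panel=panel, truth=truth,
                        config=cfg, seed=cfg.seed)


# ---------------------------------------------------------------------------
# serialization


def write_trial_csvs(dataset: TrialDataset, outdir) -> Dict[str, str]:
    """Write the dataset as the package's CSV/VCF interchange files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _w(name, df):
        p = os.path.join(outdir, name)
        df.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p

    _w("design.csv", dataset.design.plots)
    _w("genotype_meta.csv", dataset.design.genotype_meta)
    _w("heights.csv", dataset.heights_frame())
    _w("temperature.csv", dataset.temperature_frame())
    truth = dataset.truth.values.reset_index(names="genotype")
    _w("truth.csv", truth)
    dm = pd.DataFrame(dataset.panel.genotypes,
                      index=dataset.panel.genotype_ids,
                      columns=dataset.panel.map["marker"])
    p = os.path.join(outdir, "markers.csv")
    dm.to_csv(p, index_label="genotype")
    paths["markers.csv"] = p
    _w("marker_map.csv", dataset.panel.map)
    paths["markers.vcf"] = write_vcf(dataset.panel,
                                     os.path.join(outdir, "markers.vcf"))
    return paths


def write_vcf(panel: MarkerPanel, path) -> str:
    """Write the panel as a minimal diploid VCFv4.2 (GT field, unphased)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stemtherm.simdata\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.genotype_ids) + "\n")
        for m, rec in enumerate(panel.map.itertuples()):
            calls = [gt_map.get(g, "./.") if not np.isnan(g) else "./."
                     for g in panel.genotypes[:, m]]
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.marker}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")
    return str(path)


def read_vcf(path) -> MarkerPanel:
    """Read a diploid VCF into a MarkerPanel (dosage of the ALT allele).

    Uses cyvcf2 when importable, falling back to a plain-text reader for the
    minimal VCFs this package writes.  Multi-allelic sites are dropped.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None:
        v = VCF(str(path))
        ids = list(v.samples)
        rows, chroms, poss, names = [], [], [], []
        for rec in v:
            if len(rec.ALT) != 1:
                continue
            g = rec.genotype.array()[:, :2].astype(float)
            g[g < 0] = np.nan
            rows.append(np.nansum(g, axis=1) + np.where(np.isnan(g).all(axis=1),
                                                        np.nan, 0.0))
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            names.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        genotypes = np.array(rows).T
    else:
        ids, rows, chroms, poss, names = [], [], [], [], []
        code = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0,
                "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    ids = parts[9:]
                    continue
                if "," in parts[4]:
                    continue
                chroms.append(parts[0])
                poss.append(int(parts[1]))
                names.append(parts[2])
                rows.append([code.get(x.split(":")[0], np.nan)
                             for x in parts[9:]])
        genotypes = np.array(rows, float).T
    map_df = pd.DataFrame({"chrom": chroms, "pos": poss, "marker": names})
    return MarkerPanel(genotype_ids=ids, genotypes=genotypes, map=map_df)
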