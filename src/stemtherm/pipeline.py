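"""End-to-end pipeline: simulate -> extract -> fit -> aggregate -> genetics.

``run_pipeline`` executes the stage-wise workflow as a reproducible run:

1. ``simulate``       generate (or load) a trial dataset,
2. ``extract-traits`` monotone P-spline + QMER phenology per plot,
3. ``fit-response``   asymptotic dose-response + linear slope per plot,
4. ``adjust``         stage-2 within-year adjustment and stage-3
                      across-year BLUEs/BLUPs per trait,
5. ``genetics``       kinship, heritabilities, GBLUP CV, phenotypic and
                      genetic correlations, group summaries,
6. ``gwas``           single-locus MLM GWAS per trait.

Each stage writes CSV outputs carrying the run-manifest hash in a header
comment; completed stages are skipped when a run is resumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import growthcurves, quantgen, simdata, stagewise
from .doseresponse import fit_asymptotic, fit_linear_slope
from .simdata import SimConfig, TrialDataset

log = logging.getLogger("stemtherm")

TRAITS = ["tPHstart", "tPHstop", "PH_max", "T_min", "r_max", "lrc", "lm_slope"]
ALL_STAGES = ["simulate", "extract-traits", "fit-response", "adjust",
              "genetics", "gwas"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    traits: List[str] = field(default_factory=lambda: list(TRAITS))
    window_pad_days: float = 3.0
    n_starts: int = 8
    use_markers: bool = True
    n_pc: int = 3
    gwas_alpha: float = 0.05
    cv_folds: int = 10
    cv_repeats: int = 10
    genetic_corr_pairs: Optional[List[List[str]]] = None
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["sim"].get("sigma_g"), pd.DataFrame):
            d["sim"]["sigma_g"] = d["sim"]["sigma_g"].to_numpy().tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            if sim.get("sigma_g") is not None:
                sim["sigma_g"] = pd.DataFrame(np.asarray(sim["sigma_g"]))
            for key in ("years",):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)

    def manifest_hash(self) -> str:
        # the hash identifies the scientific configuration, not where the
        # outputs land
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: str, run_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# stemtherm run {run_hash}\n")
        df.to_csv(fh, index=False, float_format="%.8g")


def read_output_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def extract_plot_traits(dataset: TrialDataset, window_pad_days: float = 3.0,
                        n_starts: int = 8, traits: List[str] = None,
                        seed: int = 0) -> pd.DataFrame:
    """Plot-level trait table (stage 1): phenology + dose-response per plot."""
    traits = traits or TRAITS
    want_response = any(t in traits for t in ("T_min", "r_max", "lrc"))
    want_linear = "lm_slope" in traits
    records = []
    for rec in dataset.design.plots.itertuples():
        hs = dataset.heights[rec.plot_id]
        temps = dataset.temperature[rec.year]
        row: Dict[str, object] = {
            "plot_id": rec.plot_id, "year": rec.year, "rep": rec.rep,
            "row": rec.row, "range": rec.range, "genotype": rec.genotype,
            "is_check": rec.is_check,
        }
        flags = []
        try:
            ph = growthcurves.extract_phenology(hs.times, hs.heights)
            row["tPHstart"] = ph.tPHstart
            row["tPHstop"] = ph.tPHstop
            row["PH_max"] = ph.PH_max
            flags.extend(ph.flags)
        except growthcurves.UnfitTableError as exc:
            row.update({"tPHstart": None, "tPHstop": None, "PH_max": None})
            flags.append(str(exc))
            ph = None
        if ph is not None and (want_response or want_linear):
            t_a = (ph.tPHstart - window_pad_days if ph.tPHstart is not None
                   else hs.times[0])
            t_b = (ph.tPHstop + window_pad_days if ph.tPHstop is not None
                   else hs.times[-1])
            t_b = min(t_b, temps.times[-1])
            if want_response:
                fit = fit_asymptotic(hs.times, hs.heights, temps.times,
                                     temps.values, (t_a, t_b),
                                     n_starts=n_starts, seed=seed)
                if fit.status == "ok":
                    row["T_min"] = fit.params.T_min
                    row["r_max"] = fit.params.r_max
                    row["lrc"] = fit.params.lrc
                    flags.extend(fit.flags)
                else:
                    row.update({"T_min": None, "r_max": None, "lrc": None})
                    flags.append(f"dose-response {fit.status}")
            if want_linear:
                try:
                    lin = fit_linear_slope(hs.times, hs.heights, temps.times,
                                           temps.values, (t_a, t_b))
                    row["lm_slope"] = lin.lm_slope
                except ValueError as exc:
                    row["lm_slope"] = None
                    flags.append(f"lm_slope: {exc}")
        row["flags"] = "; ".join(flags)
        records.append(row)
    return pd.DataFrame(records)


def run_pipeline(config: RunConfig, resume: bool = False) -> str:
    """Execute the configured stages; returns the run directory."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    run_hash = config.manifest_hash()
    log.setLevel(logging.INFO)
    fh = logging.FileHandler(os.path.join(out, "run.log"))
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    t_start = time.time()

    manifest = {
        "config": config.to_dict(), "hash": run_hash,
        "seed": config.seed, "stages": config.stages,
        "versions": _versions(),
    }
    with open(os.path.join(out, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, default=str)

    def done(name):
        return resume and os.path.exists(os.path.join(out, name))

    stages = config.stages
    dataset = None

    try:
        # --- simulate -----------------------------------------------------
        if "simulate" in stages:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            dataset = simdata.simulate_trial(sim_cfg)
            if not done("design.csv"):
                simdata.write_trial_csvs(dataset, out)
                log.info("simulate: %d plots, %d genotypes, %d markers",
                         len(dataset.design.plots), dataset.panel.n_geno,
                         dataset.panel.n_markers)

        # --- extract + fit ------------------------------------------------
        trait_path = os.path.join(out, "traits.csv")
        if not done("traits.csv"):
            tt = extract_plot_traits(dataset, config.window_pad_days,
                                     config.n_starts, config.traits,
                                     seed=config.seed)
            _write_csv(tt, trait_path, run_hash)
            log.info("traits: %d plots extracted", len(tt))
        traits_df = read_output_csv(trait_path)

        # --- stage 2 + 3 ----------------------------------------------------
        if "adjust" in stages:
            s2_rows, s3_rows = [], []
            kin = None
            kin_ids = None
            if config.use_markers and dataset is not None:
                fpanel, _ = quantgen.filter_markers(dataset.panel)
                kin = quantgen.ibs_kinship(fpanel)
                kin_ids = kin.genotype_ids
            stage2_by_trait = {}
            for trait in [t for t in config.traits if t in traits_df]:
                per_year = []
                for year, sub in traits_df.groupby("year"):
                    if sub[trait].notna().sum() < 10:
                        continue
                    s2 = stagewise.stage2_adjust(sub, year, trait=trait)
                    per_year.append(s2)
                    t = s2.table.copy()
                    t.insert(0, "trait", trait)
                    t.insert(1, "year", year)
                    t["H2_j"] = s2.H2_j
                    s2_rows.append(t)
                if not per_year:
                    continue
                stage2_by_trait[trait] = per_year
                s3_blue = stagewise.stage3_combine(per_year, mode="BLUE",
                                                   use_weights="auto")
                s3_blup = stagewise.stage3_combine(
                    per_year, mode="BLUP", kinship=kin.matrix if kin else None,
                    kin_ids=kin_ids, use_weights="on" if s3_blue.weighted else "off")
                merged = pd.DataFrame({
                    "trait": trait,
                    "genotype": s3_blue.genotype_values.index,
                    "blue": s3_blue.genotype_values.to_numpy(),
                    "se": s3_blue.genotype_se.to_numpy(),
                })
                merged["blup"] = merged["genotype"].map(s3_blup.genotype_values)
                merged["H2_delta_blup"] = s3_blup.H2_delta_blup
                merged["weighted"] = s3_blue.weighted
                s3_rows.append(merged)
            _write_csv(pd.concat(s2_rows, ignore_index=True),
                       os.path.join(out, "stage2.csv"), run_hash)
            _write_csv(pd.concat(s3_rows, ignore_index=True),
                       os.path.join(out, "stage3.csv"), run_hash)
            log.info("adjust: stage-2/3 complete for %d traits", len(s3_rows))

        # --- genetics -------------------------------------------------------
        stage3_df = None
        if os.path.exists(os.path.join(out, "stage3.csv")):
            stage3_df = read_output_csv(os.path.join(out, "stage3.csv"))
        if "genetics" in stages:
            if not config.use_markers or dataset is None:
                log.info("genetics: skipped (no marker data configured)")
            else:
                _genetics_stage(config, dataset, traits_df, stage3_df, out,
                                run_hash)
        if "gwas" in stages:
            if not config.use_markers or dataset is None:
                log.info("gwas: skipped (no marker data configured)")
            else:
                _gwas_stage(config, dataset, stage3_df, out, run_hash)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()

    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return out


def _genetics_stage(config, dataset, traits_df, stage3_df, out, run_hash):
    fpanel, report = quantgen.filter_markers(dataset.panel)
    kin = quantgen.ibs_kinship(fpanel)
    _write_csv(kin.as_frame().reset_index(names="genotype"),
               os.path.join(out, "kinship.csv"), run_hash)
    ld = quantgen.ld_decay_threshold(fpanel, seed=config.seed)
    _write_csv(ld.per_chrom, os.path.join(out, "ld_decay.csv"), run_hash)

    # Table-1-shaped summary: per-year repeatability, across-year
    # heritability, GBLUP accuracy
    stage2_df = read_output_csv(os.path.join(out, "stage2.csv"))
    summary_rows = []
    for trait in [t for t in config.traits if stage3_df is not None
                  and t in set(stage3_df["trait"])]:
        sub3 = stage3_df[stage3_df["trait"] == trait]
        blues = sub3.set_index("genotype")["blue"].dropna()
        weights = 1.0 / sub3.set_index("genotype")["se"].loc[blues.index] ** 2
        try:
            cv = quantgen.gblup_cv(blues, kin, weights=weights,
                                   k=config.cv_folds, repeats=config.cv_repeats,
                                   seed=config.seed)
            acc, acc_var = cv.mean_r, cv.var_r
        except ValueError as exc:
            log.warning("gblup %s: %s", trait, exc)
            acc, acc_var = np.nan, np.nan
        row = {"trait": trait,
               "H2_delta_blup": sub3["H2_delta_blup"].iloc[0],
               "gblup_r": acc, "gblup_r_var": acc_var}
        for year, s2y in stage2_df[stage2_df["trait"] == trait].groupby("year"):
            row[f"H2_j_{year}"] = s2y["H2_j"].iloc[0]
        summary_rows.append(row)
    _write_csv(pd.DataFrame(summary_rows),
               os.path.join(out, "summary.csv"), run_hash)

    # phenotypic correlations on plot values
    pheno_rows = []
    avail = [t for t in config.traits if t in traits_df]
    for i, t1 in enumerate(avail):
        for t2 in avail[i + 1:]:
            pc = quantgen.phenotypic_correlations(traits_df, t1, t2)
            pc.insert(0, "trait1", t1)
            pc.insert(1, "trait2", t2)
            pheno_rows.append(pc)
    if pheno_rows:
        _write_csv(pd.concat(pheno_rows, ignore_index=True),
                   os.path.join(out, "pheno_corr.csv"), run_hash)

    # genetic correlations on stage-2 BLUEs
    s2_long = stage2_df.rename(columns={"blue": "blue"})[
        ["trait", "year", "genotype", "blue"]]
    pairs = config.genetic_corr_pairs
    if pairs is None:
        pairs = [[t1, t2] for i, t1 in enumerate(avail)
                 for t2 in avail[i + 1:]]
    g_rows = []
    for t1, t2 in pairs:
        try:
            gc = quantgen.genetic_correlation(s2_long, t1, t2, kin)
            g_rows.append({"trait1": t1, "trait2": t2,
                           "r_g": gc.correlation, "cov_g": gc.cov_g,
                           "var_g1": gc.var_g1, "var_g2": gc.var_g2,
                           "converged": gc.converged,
                           "flags": "; ".join(gc.flags)})
        except ValueError as exc:
            g_rows.append({"trait1": t1, "trait2": t2, "r_g": np.nan,
                           "flags": str(exc)})
    _write_csv(pd.DataFrame(g_rows), os.path.join(out, "genetic_corr.csv"),
               run_hash)

    # country-group summaries of across-year BLUEs
    meta = dataset.design.genotype_meta.set_index("genotype")
    grp_rows = []
    for trait in avail:
        if stage3_df is None or trait not in set(stage3_df["trait"]):
            continue
        sub3 = stage3_df[stage3_df["trait"] == trait].set_index("genotype")
        vals = sub3["blue"].dropna()
        common = vals.index.intersection(meta.index)
        try:
            gs = quantgen.group_summary(vals.loc[common],
                                        meta.loc[common, "country"],
                                        era=meta.loc[common, "era"])
            t = gs.table.copy()
            t.insert(0, "trait", trait)
            grp_rows.append(t)
        except ValueError as exc:
            log.warning("group summary %s: %s", trait, exc)
    if grp_rows:
        _write_csv(pd.concat(grp_rows, ignore_index=True),
                   os.path.join(out, "groups.csv"), run_hash)


def _gwas_stage(config, dataset, stage3_df, out, run_hash):
    fpanel, _ = quantgen.filter_markers(dataset.panel)
    kin = quantgen.ibs_kinship(fpanel)
    for trait in [t for t in config.traits if stage3_df is not None
                  and t in set(stage3_df["trait"])]:
        sub3 = stage3_df[stage3_df["trait"] == trait]
        blues = sub3.set_index("genotype")["blue"].dropna()
        try:
            res = quantgen.gwas_mlm(blues, fpanel, kin, n_pc=config.n_pc,
                                    alpha=config.gwas_alpha)
        except ValueError as exc:
            log.warning("gwas %s: %s", trait, exc)
            continue
        _write_csv(res.table, os.path.join(out, f"gwas_{trait}.csv"), run_hash)


def _versions() -> dict:
    import scipy
    import stemtherm
    return {"stemtherm": getattr(stemtherm, "__version__", "dev"),
            "numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__}
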