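"""Stage-wise weighted mixed-model aggregation of plot-level traits.

Stage 2 (within year): plot values of one trait are adjusted for spatial
field gradients with a mixed model

    trait = genotype + row (random) + range (random) + error,

run once with genotype fixed (adjusted genotype-year means, BLUEs, with
standard errors whose inverse squares become next-stage weights) and once
with genotype random (repeatability H2_j from BLUP difference variances).

Stage 3 (across years): the year x genotype BLUEs are combined with

    value_ij = mu + year_j + genotype_i + gxy_ij + e_ij,

where the genotype-by-year interaction has a year-specific (diagonal)
variance and residuals are weighted by the stage-2 weights.  With genotype
fixed this yields across-year BLUEs; with genotype random and a known
kinship it yields genomic BLUPs and the difference-based heritability

    H2 = 1 - mean pairwise PEV of BLUP differences / (2 sigma2_g).

Weighting is kept only when it lowers the Bayesian information criterion
(mode "auto").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lmm import (LmmFit, RandomTerm, build_design, mean_pairwise_pev_difference,
                  reml_lmm)


@dataclass
class Stage2Result:
    year: int
    table: pd.DataFrame          # genotype, blue, se, weight
    H2_j: float
    varcomp_blup: dict
    varcomp_blue: dict
    flags: list = field(default_factory=list)


@dataclass
class Stage3Result:
    mode: str                    # "BLUE" | "BLUP"
    genotype_values: pd.Series   # BLUEs (mode BLUE) or BLUPs (mode BLUP)
    genotype_se: Optional[pd.Series]
    year_effects: pd.Series
    varcomp: dict
    H2_delta_blup: Optional[float]
    bic: float
    weighted: bool
    fit: LmmFit = None
    flags: list = field(default_factory=list)


def heritability_vblup(fit: LmmFit, term: str = "genotype"):
    """Difference-based heritability H2 = 1 - vbar_delta / (2 sigma2_g).

    ``fit`` must have been run with ``compute_pev=[term]``.  Returns
    (H2, flags); H2 is clamped to [0, 1] and is 0 (flagged) when the
    genotype variance component vanishes.
    """
    sigma2_g = fit.varcomp[term]
    # a variance ratio at the optimizer's lower bound means "zero variance";
    # the PEV/variance ratio would otherwise converge to a spurious constant
    if sigma2_g <= 1e-12 or fit.gammas.get(term, 1.0) <= 1e-5:
        return 0.0, ["zero genotype variance"]
    vbar = mean_pairwise_pev_difference(fit.blup_pev[term])
    h2 = 1.0 - vbar / (2.0 * sigma2_g)
    flags = []
    if h2 < 0.0:
        h2, flags = 0.0, ["H2 clamped to 0"]
    elif h2 > 1.0:
        h2, flags = 1.0, ["H2 clamped to 1"]
    return float(h2), flags


def stage2_adjust(data: pd.DataFrame, year: int, trait: str = "value",
                  spatial: bool = True) -> Stage2Result:
    """Within-year spatially adjusted genotype means and repeatability.

    ``data`` must have columns genotype, row, range and the trait, one row
    per plot of the given year.  Rows with missing trait values are dropped.
    """
    df = data.dropna(subset=[trait]).copy()
    if spatial:
        df["row"] = df["row"].astype(str)
        df["range"] = df["range"].astype(str)
    flags = []
    counts = df["genotype"].value_counts()
    if (counts < 2).all():
        flags.append("no replication: raw values with unit weights")
        tab = (df.groupby("genotype")[trait].mean().rename("blue")
                 .reset_index())
        tab["se"] = np.nan
        tab["weight"] = 1.0
        return Stage2Result(year=year, table=tab, H2_j=np.nan,
                            varcomp_blup={}, varcomp_blue={}, flags=flags)

    random = ([RandomTerm("row", factor="row"),
               RandomTerm("range", factor="range")] if spatial else [])

    # BLUE run: genotype fixed, cell-means coding
    X, names = build_design(df, fixed=[], cell_means="genotype")
    fit_blue = reml_lmm(df, trait, X, names, random=random)
    levels = [nm[len("genotype["):-1] for nm in names]
    blue = pd.Series(fit_blue.beta.to_numpy(), index=levels)
    se = pd.Series(np.sqrt(np.diag(fit_blue.beta_cov)), index=levels)
    tab = pd.DataFrame({"genotype": levels, "blue": blue.to_numpy(),
                        "se": se.to_numpy()})
    tab["weight"] = 1.0 / tab["se"] ** 2

    # BLUP run: genotype random, for repeatability
    Xb, nb = build_design(df, fixed=[])
    fit_blup = reml_lmm(df, trait, Xb, nb,
                        random=[RandomTerm("genotype", factor="genotype")] + random,
                        compute_pev=["genotype"])
    h2, h2_flags = heritability_vblup(fit_blup, "genotype")
    return Stage2Result(year=year, table=tab, H2_j=h2,
                        varcomp_blup=fit_blup.varcomp,
                        varcomp_blue=fit_blue.varcomp,
                        flags=flags + h2_flags)


def _fit_stage3(df: pd.DataFrame, mode: str, kinship, kin_ids,
                use_weights: bool) -> Stage3Result:
    df = df.copy()
    df["year"] = df["year"].astype(str)
    years = list(pd.unique(df["year"]))
    multi_year = len(years) > 1
    if mode == "BLUE" and not multi_year and \
            df["genotype"].value_counts().max() == 1:
        # saturated single-year case: across-year BLUEs are the stage-2 BLUEs
        vals = df.set_index("genotype")["blue"]
        ses = (df.set_index("genotype")["se"] if "se" in df
               else pd.Series(np.nan, index=vals.index))
        return Stage3Result(mode="BLUE", genotype_values=vals, genotype_se=ses,
                            year_effects=pd.Series(dtype=float), varcomp={},
                            H2_delta_blup=None, bic=np.nan,
                            weighted=use_weights,
                            flags=["single-year passthrough"])
    random = []
    if multi_year:
        random.append(RandomTerm("gxy", per_row_group="year"))
    weights_col = "weight" if use_weights else None

    if mode == "BLUE":
        X, names = build_design(df, fixed=["year"] if multi_year else [],
                                cell_means="genotype")
        fit = reml_lmm(df, "blue", X, names, random=random,
                       weights=weights_col)
        levels = [nm[len("genotype["):-1] for nm in names
                  if nm.startswith("genotype[")]
        g_idx = [i for i, nm in enumerate(names) if nm.startswith("genotype[")]
        beta = fit.beta.to_numpy()
        cov = fit.beta_cov.to_numpy()
        # genotype value averaged over year effects (reference year = 0)
        y_idx = [i for i, nm in enumerate(names) if nm.startswith("year[")]
        L = np.zeros((len(g_idx), len(names)))
        for r, gi in enumerate(g_idx):
            L[r, gi] = 1.0
            for yi in y_idx:
                L[r, yi] = 1.0 / len(years)
        vals = pd.Series(L @ beta, index=levels)
        ses = pd.Series(np.sqrt(np.diag(L @ cov @ L.T)), index=levels)
        year_eff = pd.Series(beta[y_idx],
                             index=[names[i] for i in y_idx])
        return Stage3Result(mode="BLUE", genotype_values=vals, genotype_se=ses,
                            year_effects=year_eff, varcomp=fit.varcomp,
                            H2_delta_blup=None, bic=fit.bic,
                            weighted=use_weights, fit=fit)

    if mode == "BLUP":
        if kinship is not None:
            kin_ids = list(kin_ids)
            df = df[df["genotype"].isin(kin_ids)].copy()
            present = [g for g in kin_ids if g in set(df["genotype"])]
            if len(present) < len(kin_ids):
                K = pd.DataFrame(kinship, index=kin_ids, columns=kin_ids)
                K = K.loc[present, present].to_numpy()
            else:
                K = np.asarray(kinship, float)
            term = RandomTerm("genotype", factor="genotype",
                              relationship=K, levels=present)
        else:
            term = RandomTerm("genotype", factor="genotype")
        X, names = build_design(df, fixed=["year"] if multi_year else [])
        fit = reml_lmm(df, "blue", X, names, random=[term] + random,
                       weights=weights_col, compute_pev=["genotype"])
        h2, flags = heritability_vblup(fit, "genotype")
        vals = fit.blup("genotype")
        y_idx = [nm for nm in names if nm.startswith("year[")]
        return Stage3Result(mode="BLUP", genotype_values=vals, genotype_se=None,
                            year_effects=fit.beta[y_idx], varcomp=fit.varcomp,
                            H2_delta_blup=h2, bic=fit.bic,
                            weighted=use_weights, fit=fit, flags=flags)
    raise ValueError(f"unknown mode {mode!r}")


def stage3_combine(stage2_tables, mode: str = "BLUE", kinship=None,
                   kin_ids=None, use_weights: str = "auto") -> Stage3Result:
    """Across-year combination of stage-2 adjusted genotype-year means.

    ``stage2_tables`` is either a list of :class:`Stage2Result` or a long
    data frame with columns year, genotype, blue, weight.
    ``use_weights``: "on", "off", or "auto" (keep weighting only when it
    lowers BIC).
    """
    if isinstance(stage2_tables, pd.DataFrame):
        df = stage2_tables.copy()
    else:
        parts = []
        for s2 in stage2_tables:
            t = s2.table.copy()
            t["year"] = s2.year
            parts.append(t)
        df = pd.concat(parts, ignore_index=True)
    df = df.dropna(subset=["blue"])
    if "weight" not in df or df["weight"].isna().any():
        df["weight"] = df.get("weight", pd.Series(1.0, index=df.index)).fillna(1.0)

    if use_weights == "on":
        return _fit_stage3(df, mode, kinship, kin_ids, True)
    if use_weights == "off":
        return _fit_stage3(df, mode, kinship, kin_ids, False)
    fit_w = _fit_stage3(df, mode, kinship, kin_ids, True)
    fit_u = _fit_stage3(df, mode, kinship, kin_ids, False)
    return select_weighting(fit_w, fit_u)


def select_weighting(weighted: Stage3Result, unweighted: Stage3Result) -> Stage3Result:
    """Keep the weighted fit only when it strictly lowers BIC (ties: unweighted)."""
    if weighted.fit is None or unweighted.fit is None:
        return unweighted
    if weighted.fit.n != unweighted.fit.n:
        raise ValueError("fits are not comparable: different row counts")
    return weighted if weighted.bic < unweighted.bic else unweighted
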