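"""Quantitative genetics: kinship, LD, GBLUP, genetic correlations, GWAS.

Everything here operates on the filtered allele-dosage panel from
:mod:`stemtherm.simdata`:

* marker QC (missingness, MAF, monomorphism, map requirement),
* normalized identity-by-state (IBS) kinship,
* chromosome-specific LD-decay distance thresholds (r^2 < cutoff),
* marker principal components for population structure,
* GBLUP genomic prediction with repeated k-fold cross-validation,
* bivariate REML genetic correlations between traits,
* per-year phenotypic (Pearson) correlations of plot values,
* single-locus mixed-linear-model GWAS with a kinship random effect,
  marker-PC covariates, and a Bonferroni significance threshold,
* country-group / registration-era summaries with Tukey HSD letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.optimize import minimize_scalar

from .simdata import MarkerPanel


# ---------------------------------------------------------------------------
# marker QC


@dataclass
class FilterReport:
    n_input: int
    n_monomorphic: int
    n_unmapped: int
    n_high_missing: int
    n_low_maf: int
    n_kept: int


def filter_markers(panel: MarkerPanel, max_missing: float = 0.05,
                   min_maf: float = 0.05, require_mapped: bool = True
                   ) -> Tuple[MarkerPanel, FilterReport]:
    """QC filter: drop monomorphic, unmapped, high-missing and rare markers."""
    g = panel.genotypes
    n, m = g.shape
    keep = np.ones(m, bool)
    miss = np.isnan(g).mean(axis=0)
    freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    unmapped = np.zeros(m, bool)
    if require_mapped:
        unmapped = (panel.map["chrom"].isna() | panel.map["pos"].isna()).to_numpy()
    mono = np.array([len(np.unique(g[~np.isnan(g[:, j]), j])) <= 1
                     for j in range(m)])
    high_missing = miss > max_missing
    low_maf = maf < min_maf

    keep &= ~unmapped
    keep &= ~mono
    keep &= ~high_missing
    keep &= ~low_maf
    report = FilterReport(n_input=m, n_monomorphic=int(mono.sum()),
                          n_unmapped=int(unmapped.sum()),
                          n_high_missing=int(high_missing.sum()),
                          n_low_maf=int((low_maf & ~mono).sum()),
                          n_kept=int(keep.sum()))
    if report.n_kept == 0:
        raise ValueError("all markers removed by QC filters")
    out = MarkerPanel(genotype_ids=list(panel.genotype_ids),
                      genotypes=g[:, keep],
                      map=panel.map.loc[keep].reset_index(drop=True),
                      subpop=panel.subpop)
    return out, report


# ---------------------------------------------------------------------------
# kinship


@dataclass
class Kinship:
    genotype_ids: list
    matrix: np.ndarray           # normalized IBS
    raw: np.ndarray              # raw mean IBS similarities
    normalization: str = "minmax"
    psd_repaired: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.genotype_ids,
                            columns=self.genotype_ids)


def raw_ibs(panel: MarkerPanel) -> np.ndarray:
    """Mean identity-by-state similarity, (2 - |g_i - g_j|) / 2 over shared loci."""
    g = panel.genotypes
    n = g.shape[0]
    obs = (~np.isnan(g)).astype(float)
    gz = np.nan_to_num(g, nan=0.0)
    # sum over shared loci of |gi - gj| via the identity
    # |a-b| for dosages in {0,1,2}: compute with one-hot expansion
    onehot = np.stack([(gz == k) & (obs > 0) for k in (0, 1, 2)], axis=0).astype(float)
    shared = obs @ obs.T
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(f"genotypes {i} and {j} share no genotyped loci")
    absdiff = np.zeros((n, n))
    for a in range(3):
        for b in range(3):
            if a == b:
                continue
            absdiff += abs(a - b) * (onehot[a] @ onehot[b].T)
    sim = (2.0 * shared - absdiff) / (2.0 * shared)
    return sim


def ibs_kinship(panel: MarkerPanel, normalize: bool = True,
                psd_floor: float = 1e-8) -> Kinship:
    """Normalized IBS kinship matrix.

    The raw mean-IBS matrix is min-max rescaled to span [0, 1]; a
    nearest-PSD repair (eigenvalue clipping) is applied and recorded if the
    rescaled matrix is indefinite.
    """
    raw = raw_ibs(panel)
    if normalize:
        lo, hi = raw.min(), raw.max()
        mat = (raw - lo) / (hi - lo) if hi > lo else raw.copy()
    else:
        mat = raw.copy()
    mat = (mat + mat.T) / 2.0
    w, V = np.linalg.eigh(mat)
    repaired = False
    if w.min() < 0:
        mat = V @ np.diag(np.clip(w, psd_floor, None)) @ V.T
        mat = (mat + mat.T) / 2.0
        repaired = True
    return Kinship(genotype_ids=list(panel.genotype_ids), matrix=mat, raw=raw,
                   normalization="minmax" if normalize else "none",
                   psd_repaired=repaired)


# ---------------------------------------------------------------------------
# LD decay


@dataclass
class LdDecayResult:
    cutoff: float
    per_chrom: pd.DataFrame      # chrom, threshold_bp, n_pairs, flag


def ld_decay_threshold(panel: MarkerPanel, cutoff: float = 0.2,
                       max_pairs: int = 20000, min_pairs: int = 50,
                       seed: int = 0) -> LdDecayResult:
    """Chromosome-specific distance where expected r^2 decays below cutoff.

    Squared dosage correlations of sampled intra-chromosomal pairs are
    smoothed with a monotonically decreasing isotonic fit against distance;
    the threshold is the smallest sampled distance whose fitted r^2 drops
    below the cutoff.  If the curve never crosses, the chromosome length is
    returned with a flag.
    """
    rng = np.random.default_rng(seed)
    g = panel.imputed()
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    rows = []
    for chrom, sub in panel.map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        idx = idx[sd[idx] > 0]
        m = len(idx)
        n_all = m * (m - 1) // 2
        if n_all < min_pairs:
            rows.append((chrom, np.nan, n_all, "too few pairs"))
            continue
        if n_all <= max_pairs:
            ii, jj = np.triu_indices(m, k=1)
        else:
            ii = rng.integers(0, m, size=int(max_pairs * 1.3))
            jj = rng.integers(0, m, size=int(max_pairs * 1.3))
            ok = ii < jj
            ii, jj = ii[ok][:max_pairs], jj[ok][:max_pairs]
        a, b = idx[ii], idx[jj]
        pos = panel.map["pos"].to_numpy()
        dist = np.abs(pos[a] - pos[b]).astype(float)
        r = (g[:, a] * g[:, b]).mean(axis=0) / (sd[a] * sd[b])
        r2 = r ** 2
        order = np.argsort(dist)
        dist_s, r2_s = dist[order], r2[order]
        fitted = _pava_decreasing(r2_s)
        below = fitted < cutoff
        chrom_len = float(pos[idx].max() - pos[idx].min())
        if not below.any():
            rows.append((chrom, chrom_len, len(dist), "no decay below cutoff"))
        else:
            rows.append((chrom, float(dist_s[below][0]), len(dist), ""))
    df = pd.DataFrame(rows, columns=["chrom", "threshold_bp", "n_pairs", "flag"])
    return LdDecayResult(cutoff=cutoff, per_chrom=df)


def _pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Least-squares non-increasing fit via pool-adjacent-violators."""
    z = -np.asarray(y, float)
    vals: list = []
    wts: list = []
    for v in z:
        vals.append(v)
        wts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2 = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            w2 = wts[-2] + wts[-1]
            vals = vals[:-2] + [v2]
            wts = wts[:-2] + [w2]
    out = np.concatenate([np.full(w, v) for v, w in zip(vals, wts)])
    return -out


# ---------------------------------------------------------------------------
# PCA


def marker_pca(panel: MarkerPanel, n_pc: int = 3):
    """First ``n_pc`` principal-component scores of the centered dosage matrix.

    Returns (scores: n_geno x n_pc, variance_explained fractions).
    """
    if n_pc >= panel.n_geno:
        raise ValueError("n_pc must be smaller than the number of genotypes")
    M = panel.imputed()
    M = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    scores = U[:, :n_pc] * s[:n_pc]
    var_exp = (s ** 2) / np.sum(s ** 2)
    return scores, var_exp[:n_pc]


# ---------------------------------------------------------------------------
# GBLUP + cross-validation


def _gblup_reml(y: np.ndarray, K: np.ndarray, weights: Optional[np.ndarray] = None):
    """REML for y = mu + g + e, g ~ N(0, s2g K), e ~ N(0, s2e diag(1/w)).

    Returns (mu, s2g, s2e).  Scalar optimization over the log variance
    ratio; the residual scale is profiled.
    """
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    d = 1.0 / w
    X = np.ones((n, 1))

    def neg2(log_gamma):
        gam = np.exp(log_gamma)
        H = gam * K + np.diag(d)
        try:
            c = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return 1e12, None
        logdetH = 2 * np.log(np.diag(c)).sum()
        Hi_y = np.linalg.solve(c.T, np.linalg.solve(c, y))
        Hi_X = np.linalg.solve(c.T, np.linalg.solve(c, X))
        XtHX = (X.T @ Hi_X).item()
        mu = (X.T @ Hi_y).item() / XtHX
        r = y - mu
        Hi_r = np.linalg.solve(c.T, np.linalg.solve(c, r))
        quad = float(r @ Hi_r)
        s2 = max(quad / (n - 1), 1e-14)
        val = (n - 1) * (np.log(2 * np.pi * s2) + 1) + logdetH + np.log(XtHX)
        return val, (mu, s2, gam)

    res = minimize_scalar(lambda lg: neg2(lg)[0], bounds=(-12, 12),
                          method="bounded",
                          options={"xatol": 1e-6, "maxiter": 200})
    _, aux = neg2(res.x)
    mu, s2, gam = aux
    return mu, gam * s2, s2


@dataclass
class CvAccuracy:
    mean_r: float
    var_r: float
    fold_rs: np.ndarray
    k: int
    repeats: int
    flags: list = field(default_factory=list)


def gblup_cv(phenotypes: pd.Series, kinship: Kinship, weights=None,
             k: int = 10, repeats: int = 10, seed: int = 0) -> CvAccuracy:
    """Repeated k-fold cross-validated GBLUP prediction accuracy.

    Per repeat, genotypes are randomly partitioned into ``k`` folds
    (deterministic given ``seed``); the GBLUP model is fit on training
    genotypes and held-out genotypes are predicted through the kinship.
    Accuracy is Pearson's r per fold; mean and variance over all k*repeats
    folds are returned.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = [g for g in kinship.genotype_ids if g in phenotypes.index]
    y = phenotypes.loc[ids].to_numpy(float)
    pos = {g: i for i, g in enumerate(kinship.genotype_ids)}
    sel = np.array([pos[g] for g in ids])
    K = kinship.matrix[np.ix_(sel, sel)]
    if weights is not None:
        w = pd.Series(weights).loc[ids].to_numpy(float)
    else:
        w = np.ones(len(ids))
    n = len(ids)
    if n // k < 3:
        raise ValueError("folds would contain fewer than 3 genotypes")
    rng = np.random.default_rng(seed)
    rs = []
    flags = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold in folds:
            test = np.zeros(n, bool)
            test[fold] = True
            tr = ~test
            mu, s2g, s2e = _gblup_reml(y[tr], K[np.ix_(tr, tr)], w[tr])
            V = s2g * K[np.ix_(tr, tr)] + s2e * np.diag(1.0 / w[tr])
            alpha = np.linalg.solve(V, y[tr] - mu)
            pred = mu + s2g * K[np.ix_(test, tr)] @ alpha
            if np.std(pred) < 1e-12 or np.std(y[test]) < 1e-12:
                rs.append(0.0)
                flags.append(f"constant predictions in repeat {rep}")
            else:
                rs.append(float(np.corrcoef(pred, y[test])[0, 1]))
    rs = np.array(rs)
    return CvAccuracy(mean_r=float(rs.mean()), var_r=float(rs.var(ddof=1)),
                      fold_rs=rs, k=k, repeats=repeats, flags=flags)


# ---------------------------------------------------------------------------
# genetic correlation (bivariate REML)


@dataclass
class GeneticCorrelation:
    trait_pair: Tuple[str, str]
    correlation: Optional[float]
    cov_g: float
    var_g1: float
    var_g2: float
    resid_cov: np.ndarray
    converged: bool
    flags: list = field(default_factory=list)


def _log_chol_to_cov(params):
    """(l11, l21, l22) with diagonal on log scale -> 2x2 PSD matrix."""
    L = np.array([[np.exp(params[0]), 0.0], [params[1], np.exp(params[2])]])
    return L @ L.T


def genetic_correlation(stage2_long: pd.DataFrame, trait1: str, trait2: str,
                        kinship: Kinship) -> GeneticCorrelation:
    """Bivariate REML genetic correlation from stage-2 genotype-year means.

    ``stage2_long`` columns: genotype, year, trait, blue.  Model: trait-wise
    intercepts and year effects fixed; genotype effects jointly distributed
    with a 2x2 genetic covariance Kronecker the kinship; a single combined
    2x2 residual covariance across traits (genotype-by-year and residual are
    confounded at one observation per cell and are pooled).  Requires
    complete genotype x year x trait cells; incomplete genotypes are
    dropped.  Exploits the eigen-rotation of the kinship for an exact,
    fast REML on balanced data.
    """
    sub = stage2_long[stage2_long["trait"].isin([trait1, trait2])]
    wide = sub.pivot_table(index=["genotype", "year"], columns="trait",
                           values="blue", aggfunc="first")
    wide = wide.dropna()
    years = sorted(wide.index.get_level_values("year").unique())
    genos = sorted(wide.index.get_level_values("genotype").unique())
    # keep genotypes observed in every year and present in the kinship
    kin_set = set(kinship.genotype_ids)
    counts = wide.groupby(level="genotype").size()
    genos = [g for g in genos if counts.get(g, 0) == len(years) and g in kin_set]
    if len(genos) < 10:
        raise ValueError("too few complete genotypes for bivariate REML")
    J, T = len(years), 2
    Y = np.empty((len(genos), J, T))
    for jy, yr in enumerate(years):
        block = wide.xs(yr, level="year").loc[genos]
        Y[:, jy, 0] = block[trait1].to_numpy()
        Y[:, jy, 1] = block[trait2].to_numpy()

    pos = {g: i for i, g in enumerate(kinship.genotype_ids)}
    sel = np.array([pos[g] for g in genos])
    K = kinship.matrix[np.ix_(sel, sel)]
    w_k, U = np.linalg.eigh(K)
    w_k = np.clip(w_k, 0.0, None)
    # rotate the genotype axis: independent 8-dim blocks
    Yr = np.einsum("gc,gjt->cjt", U, Y).reshape(len(genos), J * T)
    s_c = U.sum(axis=0)
    B = np.tile(np.eye(T), (J, 1))            # (J*T, T): maps trait effects

    scale = Y.reshape(-1, T).std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Yr = Yr / np.tile(scale, J)[None, :]

    JT = J * T
    nG = len(genos)
    eyeJT = np.eye(JT)

    def neg2(params):
        Sg = _log_chol_to_cov(params[:3])
        R = _log_chol_to_cov(params[3:])
        V_base = np.kron(np.eye(J), R)
        G_big = B @ Sg @ B.T
        V_all = w_k[:, None, None] * G_big[None] + V_base[None]
        sign, logdets = np.linalg.slogdet(V_all)
        if np.any(sign <= 0):
            return 1e12, None
        try:
            Vi = np.linalg.solve(V_all, np.broadcast_to(eyeJT, V_all.shape))
        except np.linalg.LinAlgError:
            return 1e12, None
        XtVX = np.einsum("c,cij->ij", s_c ** 2, Vi)
        XtVy = np.einsum("c,cij,cj->i", s_c, Vi, Yr)
        try:
            chX = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return 1e12, None
        beta = np.linalg.solve(chX.T, np.linalg.solve(chX, XtVy))
        r = Yr - s_c[:, None] * beta[None, :]
        quad = np.einsum("ci,cij,cj->", r, Vi, r)
        logdetX = 2 * np.log(np.diag(chX)).sum()
        val = quad + logdets.sum() + logdetX
        return val, (Sg, R, beta)

    # moment-based start: between-genotype covariance of genotype means vs
    # within-genotype (across-year) covariance, on the scaled data
    Ym = Y.reshape(len(genos), J, T) / scale[None, None, :]
    gmeans = Ym.mean(axis=1)
    dev = (Ym - gmeans[:, None, :]).reshape(-1, T)
    R0 = np.cov(dev.T) * J / max(J - 1, 1) + 1e-3 * np.eye(2)
    Sg0 = np.cov(gmeans.T) - R0 / J
    w0, V0 = np.linalg.eigh(Sg0)
    Sg0 = V0 @ np.diag(np.clip(w0, 1e-3, None)) @ V0.T

    def cov_to_params(C):
        L = np.linalg.cholesky(C)
        return [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]

    x0 = np.array(cov_to_params(Sg0) + cov_to_params(R0))
    res = optimize.minimize(lambda p: neg2(p)[0], x0, method="Nelder-Mead",
                            options={"maxiter": 2500, "fatol": 1e-9,
                                     "xatol": 1e-7})
    val, aux = neg2(res.x)
    Sg, R, _ = aux
    # undo the per-trait scaling
    D = np.diag(scale)
    Sg = D @ Sg @ D
    R = D @ R @ D
    var1, var2 = Sg[0, 0], Sg[1, 1]
    flags = []
    if var1 <= 1e-10 * scale[0] ** 2 or var2 <= 1e-10 * scale[1] ** 2:
        return GeneticCorrelation((trait1, trait2), None, float(Sg[0, 1]),
                                  float(var1), float(var2), R,
                                  converged=bool(res.success),
                                  flags=["near-zero genetic variance"])
    corr = float(Sg[0, 1] / np.sqrt(var1 * var2))
    corr = float(np.clip(corr, -1.0, 1.0))
    if not res.success:
        flags.append("optimizer did not report convergence")
    return GeneticCorrelation((trait1, trait2), corr, float(Sg[0, 1]),
                              float(var1), float(var2), R,
                              converged=bool(res.success), flags=flags)


# ---------------------------------------------------------------------------
# phenotypic correlations


def phenotypic_correlations(plot_table: pd.DataFrame, trait1: str, trait2: str,
                            min_pairs: int = 3) -> pd.DataFrame:
    """Per-year Pearson correlation of plot-based trait values + summary.

    ``plot_table`` columns: year plus the two trait columns (one row per
    plot).  Years with fewer than ``min_pairs`` complete pairs are skipped.
    Returns a frame with one row per year and a "summary" row holding the
    mean, with min and max in separate columns.
    """
    rows = []
    for year, sub in plot_table.groupby("year"):
        ok = sub[[trait1, trait2]].dropna()
        if len(ok) < min_pairs:
            rows.append((str(year), np.nan, len(ok), "skipped: too few pairs"))
            continue
        r = float(np.corrcoef(ok[trait1], ok[trait2])[0, 1])
        rows.append((str(year), r, len(ok), ""))
    df = pd.DataFrame(rows, columns=["year", "r", "n", "flag"])
    vals = df["r"].dropna()
    summary = pd.DataFrame([{"year": "summary", "r": vals.mean(),
                             "n": int(df["n"].sum()), "flag": "",
                             "r_min": vals.min(), "r_max": vals.max()}])
    return pd.concat([df, summary], ignore_index=True)


# ---------------------------------------------------------------------------
# GWAS (single-locus mixed linear model)


@dataclass
class GwasResult:
    table: pd.DataFrame          # chrom, pos, marker, beta, se, stat, p, neglog10p, significant
    threshold_neglog10p: float
    n_pc: int
    h2_null: float


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """-log10 of the Bonferroni-corrected per-marker significance level."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_markers))


def gwas_mlm(phenotype: pd.Series, panel: MarkerPanel, kinship: Kinship,
             n_pc: int = 3, alpha: float = 0.05) -> GwasResult:
    """Single-locus mixed-linear-model GWAS.

    Variance components are estimated once under the no-marker null model
    (phenotype ~ intercept + marker PCs + kinship random effect) via the
    spectral decomposition of the kinship; each marker is then tested by
    generalized least squares with those fixed variance components
    ("population parameters previously determined").  Two-sided p-values
    from the t statistic; the Bonferroni threshold is attached.
    """
    ids = [g for g in panel.genotype_ids if g in phenotype.index]
    if len(ids) < 50:
        raise ValueError("phenotype must cover at least 50 genotypes")
    gpos = {g: i for i, g in enumerate(panel.genotype_ids)}
    sel = np.array([gpos[g] for g in ids])
    y = phenotype.loc[ids].to_numpy(float)
    M = panel.imputed()[sel]
    kpos = {g: i for i, g in enumerate(kinship.genotype_ids)}
    ksel = np.array([kpos[g] for g in ids])
    K = kinship.matrix[np.ix_(ksel, ksel)]

    n = len(ids)
    covs = [np.ones(n)]
    if n_pc > 0:
        sub = MarkerPanel(genotype_ids=ids, genotypes=panel.genotypes[sel],
                          map=panel.map)
        scores, _ = marker_pca(sub, n_pc=n_pc)
        covs.extend(scores.T)
    W = np.column_stack(covs)

    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ y
    Wr = U.T @ W

    p_cov = W.shape[1]

    def neg2(log_delta):
        # delta = s2e / s2g; V = s2g (K + delta I)
        delta = np.exp(log_delta)
        d = lam + delta
        WtW = (Wr / d[:, None]).T @ Wr
        Wty = (Wr / d[:, None]).T @ yr
        try:
            beta = np.linalg.solve(WtW, Wty)
        except np.linalg.LinAlgError:
            return 1e12
        r = yr - Wr @ beta
        quad = float(r @ (r / d))
        s2g = max(quad / (n - p_cov), 1e-14)
        sign, logdetW = np.linalg.slogdet(WtW)
        if sign <= 0:
            return 1e12
        return ((n - p_cov) * (np.log(2 * np.pi * s2g) + 1)
                + np.log(d).sum() + logdetW)

    res = minimize_scalar(neg2, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-5, "maxiter": 200})
    delta = float(np.exp(res.x))
    d = lam + delta
    h2_null = float(1.0 / (1.0 + delta / max(lam.mean(), 1e-12)))

    # GLS per marker with weights 1/d on the rotated scale
    Mr = U.T @ (M - M.mean(axis=0))
    sw = 1.0 / np.sqrt(d)
    Ws = Wr * sw[:, None]
    ys = yr * sw
    Ms = Mr * sw[:, None]
    # project out covariates
    Q, _ = np.linalg.qr(Ws)
    y_res = ys - Q @ (Q.T @ ys)
    M_res = Ms - Q @ (Q.T @ Ms)
    mm = (M_res ** 2).sum(axis=0)
    df_resid = n - p_cov - 1
    betas = np.full(M.shape[1], np.nan)
    ses = np.full(M.shape[1], np.nan)
    stats_t = np.full(M.shape[1], np.nan)
    pvals = np.ones(M.shape[1])
    collinear = mm < 1e-10
    ok = ~collinear
    betas[ok] = (M_res[:, ok].T @ y_res) / mm[ok]
    rss = (y_res @ y_res) - betas[ok] ** 2 * mm[ok]
    s2 = np.maximum(rss / df_resid, 1e-300)
    ses[ok] = np.sqrt(s2 / mm[ok])
    stats_t[ok] = betas[ok] / ses[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(stats_t[ok]), df=df_resid)
    pvals = np.clip(pvals, 1e-300, 1.0)

    thr = bonferroni_threshold(int(ok.sum()) if ok.sum() else M.shape[1], alpha)
    table = pd.DataFrame({
        "chrom": panel.map["chrom"].to_numpy(),
        "pos": panel.map["pos"].to_numpy(),
        "marker": panel.map["marker"].to_numpy()
        if "marker" in panel.map else np.arange(M.shape[1]),
        "beta": betas, "se": ses, "stat": stats_t, "p": pvals,
        "neglog10p": -np.log10(pvals),
    })
    table["significant"] = table["neglog10p"] >= thr
    table.loc[collinear, "significant"] = False
    flag_col = np.where(collinear, "collinear with covariates", "")
    table["flag"] = flag_col
    return GwasResult(table=table, threshold_neglog10p=thr, n_pc=n_pc,
                      h2_null=h2_null)


# ---------------------------------------------------------------------------
# group summaries


@dataclass
class GroupSummary:
    table: pd.DataFrame          # group, n, mean, se, letters
    era_trajectories: pd.DataFrame
    excluded: list


def _compact_letters(groups, pmat: pd.DataFrame, alpha: float) -> Dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different at ``alpha``.
    Ties broken by alphabetical group order.
    """
    groups = sorted(groups)
    letters: list = [set(groups)]  # start optimistic: one letter for all
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            if pmat.loc[g1, g2] >= alpha:
                continue
            expanded = []
            for s in letters:
                if g1 in s and g2 in s:
                    expanded.append(s - {g2})
                    expanded.append(s - {g1})
                else:
                    expanded.append(s)
            # absorb: drop sets contained in another set
            letters = [s for k, s in enumerate(expanded)
                       if s and not any(s <= t for t2, t in enumerate(expanded)
                                        if t2 != k and (s < t or (s == t and t2 < k)))]
    letters.sort(key=lambda s: sorted(s)[0])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for k, s in enumerate(letters):
        for g in sorted(s):
            out[g] += alphabet[k % len(alphabet)]
    return out


def group_summary(values: pd.Series, groups: pd.Series,
                  era: Optional[pd.Series] = None, alpha: float = 0.05,
                  min_group_size: int = 10) -> GroupSummary:
    """Group means, SEs and Tukey-HSD compact letter display.

    Groups with fewer than ``min_group_size`` members are excluded.  The
    letter display assigns shared letters to groups that are not
    significantly different under Tukey's honest significant difference on
    a one-way model.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df["group"].value_counts()
    eligible = sizes[sizes >= min_group_size].index.tolist()
    excluded = sorted(set(sizes.index) - set(eligible))
    df = df[df["group"].isin(eligible)]
    if df["group"].nunique() < 2:
        raise ValueError("fewer than 2 eligible groups")

    tuk = pairwise_tukeyhsd(df["value"].to_numpy(),
                            df["group"].astype(str).to_numpy(), alpha=alpha)
    res = pd.DataFrame(tuk.summary().data[1:],
                       columns=tuk.summary().data[0])
    gl = sorted(df["group"].astype(str).unique())
    pmat = pd.DataFrame(1.0, index=gl, columns=gl)
    for rec in res.itertuples():
        pmat.loc[str(rec.group1), str(rec.group2)] = float(rec._4)
        pmat.loc[str(rec.group2), str(rec.group1)] = float(rec._4)
    letters = _compact_letters(gl, pmat, alpha)

    agg = df.groupby("group")["value"].agg(["size", "mean",
                                            lambda x: x.std(ddof=1) / np.sqrt(len(x))])
    agg.columns = ["n", "mean", "se"]
    agg = agg.loc[gl]
    agg["letters"] = [letters[g] for g in agg.index]
    table = agg.reset_index().rename(columns={"index": "group"})

    if era is not None:
        edf = pd.DataFrame({"value": values, "group": groups,
                            "era": era}).dropna()
        edf = edf[edf["group"].isin(eligible)]
        traj = (edf.groupby(["group", "era"])["value"]
                .agg(["size", "mean"]).reset_index()
                .rename(columns={"size": "n"}))
    else:
        traj = pd.DataFrame(columns=["group", "era", "n", "mean"])
    return GroupSummary(table=table, era_trajectories=traj, excluded=excluded)
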