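"""Restricted maximum likelihood (REML) linear mixed models.

Dense-matrix REML solver supporting

* an arbitrary fixed-effect design matrix,
* random terms defined by a grouping factor, each with an optional known
  relationship (covariance) matrix over its levels -- e.g. a genomic kinship,
* per-row "diagonal" random terms (one independent effect per data row,
  with a separate variance per group, used for year-specific genotype-by-year
  interaction variances in single-observation-per-cell layouts),
* per-row residual weights: Var(e_i) = sigma2_e / w_i.

The residual scale is profiled out analytically; the restricted likelihood is
maximized over log variance ratios gamma_k = sigma2_k / sigma2_e.  All matrix
work goes through a Woodbury identity so that each likelihood evaluation costs
O(n q^2 + q^3) for q total random-effect levels, which is small for the trial
sizes this package targets (hundreds of genotypes, a few years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize


class SingularDesignError(ValueError):
    """Fixed-effect design is rank deficient."""


@dataclass
class RandomTerm:
    """One random term of a mixed model.

    Parameters
    ----------
    name:
        Label used for the variance component in the output.
    factor:
        Column name in the data frame giving the grouping factor.
    relationship:
        Optional known covariance matrix over the factor levels (PSD).  When
        omitted the levels are i.i.d. (identity relationship).
    levels:
        Level order for ``relationship`` rows/columns.  Required when a
        relationship matrix is supplied; otherwise inferred from the data.
    per_row_group:
        When set (a column name), the term instead places one independent
        effect on every data row, with a separate variance per level of that
        column.  ``factor``/``relationship`` are ignored in that mode.
    """

    name: str
    factor: Optional[str] = None
    relationship: Optional[np.ndarray] = None
    levels: Optional[Sequence] = None
    per_row_group: Optional[str] = None


@dataclass
class LmmFit:
    """Result of a REML fit."""

    beta: pd.Series
    beta_cov: pd.DataFrame
    varcomp: dict
    sigma2_e: float
    loglik: float
    bic: float
    n: int
    p: int
    converged: bool
    message: str = ""
    blups: dict = field(default_factory=dict)
    blup_pev: dict = field(default_factory=dict)
    term_levels: dict = field(default_factory=dict)
    gammas: dict = field(default_factory=dict)

    def blup(self, term: str) -> pd.Series:
        return pd.Series(self.blups[term], index=self.term_levels[term])


def _psd_sqrt(K: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (negative eigenvalues clipped)."""
    w, V = np.linalg.eigh(np.asarray(K, float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def build_design(data: pd.DataFrame, fixed: Sequence[str], intercept: bool = True,
                 cell_means: Optional[str] = None):
    """Build a fixed-effect design matrix from column names.

    Categorical columns are dummy-coded (first level dropped when an intercept
    is present).  ``cell_means`` names one factor to code with a full set of
    indicators and no intercept (so its coefficients are adjusted cell means).
    Returns (X, names).
    """
    cols = []
    names = []
    if cell_means is not None:
        levels = pd.unique(data[cell_means])
        for lv in levels:
            cols.append((data[cell_means] == lv).to_numpy(float))
            names.append(f"{cell_means}[{lv}]")
    elif intercept:
        cols.append(np.ones(len(data)))
        names.append("(Intercept)")
    for f in fixed:
        col = data[f]
        if col.dtype.kind in "ifu" and not isinstance(col.dtype, pd.CategoricalDtype):
            cols.append(col.to_numpy(float))
            names.append(f)
        else:
            levels = pd.unique(col)
            for lv in levels[1:]:
                cols.append((col == lv).to_numpy(float))
                names.append(f"{f}[{lv}]")
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names


class _RandomBlock:
    """Preprocessed random term: U0 columns such that the term contributes
    gamma * U0 @ U0.T to the scaled covariance H."""

    def __init__(self, term: RandomTerm, data: pd.DataFrame):
        self.term = term
        self.name = term.name
        fac = data[term.factor]
        if term.levels is not None:
            levels = list(term.levels)
        else:
            levels = list(pd.unique(fac))
        self.levels = levels
        idx = pd.Categorical(fac, categories=levels)
        codes = np.asarray(idx.codes)
        if (codes < 0).any():
            missing = sorted(set(fac) - set(levels))
            raise ValueError(
                f"random term '{term.name}': levels {missing[:5]} not in "
                "the supplied relationship matrix")
        n = len(data)
        q = len(levels)
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        self.Z = Z
        if term.relationship is not None:
            K = np.asarray(term.relationship, float)
            if K.shape != (q, q):
                raise ValueError(
                    f"random term '{term.name}': relationship matrix shape "
                    f"{K.shape} does not match {q} levels")
            self.K = K
            self.S = _psd_sqrt(K)       # K = S S'
        else:
            self.K = None
            self.S = None
        self.U0 = Z @ self.S if self.S is not None else Z


def reml_lmm(data: pd.DataFrame, response: str, X, x_names: Sequence[str],
             random: Sequence[RandomTerm], weights: Optional[str] = None,
             compute_pev: Sequence[str] = (), max_iter: int = 200,
             start_gamma: float = 0.5) -> LmmFit:
    """Fit a linear mixed model by REML.

    Parameters
    ----------
    data:
        Data frame with the response, factors, and optional weight column.
    response:
        Response column name.
    X, x_names:
        Fixed-effect design matrix (n x p) and coefficient names, e.g. from
        :func:`build_design`.
    random:
        Random terms (:class:`RandomTerm`).
    weights:
        Optional column of positive per-row weights, Var(e_i) = sigma2/w_i.
    compute_pev:
        Term names for which the full BLUP prediction-error-variance matrix
        is computed (needed for difference-based heritabilities).
    """
    y = data[response].to_numpy(float)
    n = len(y)
    X = np.asarray(X, float)
    p = X.shape[1]
    if p >= n:
        raise SingularDesignError(
            f"saturated fixed design: {p} coefficients for {n} rows")
    if p > 0 and np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(
            f"fixed design is rank deficient ({np.linalg.matrix_rank(X)} < {p}); "
            f"columns: {list(x_names)}")
    if weights is not None:
        w = data[weights].to_numpy(float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    else:
        w = np.ones(n)
    d_base = 1.0 / w

    blocks = []
    perrow_masks = []   # (name, 0/1 vector)
    for term in random:
        if term.per_row_group is not None:
            grp = data[term.per_row_group]
            for lv in pd.unique(grp):
                perrow_masks.append((f"{term.name}[{lv}]",
                                     (grp == lv).to_numpy(float)))
        else:
            blocks.append(_RandomBlock(term, data))

    n_block = len(blocks)
    n_perrow = len(perrow_masks)
    n_par = n_block + n_perrow
    U0 = (np.concatenate([b.U0 for b in blocks], axis=1)
          if n_block else np.empty((n, 0)))
    block_slices = []
    off = 0
    for b in blocks:
        qb = b.U0.shape[1]
        block_slices.append(slice(off, off + qb))
        off += qb
    qtot = off

    def _assemble(log_gamma):
        g = np.exp(np.clip(log_gamma, -30.0, 30.0))
        d = d_base.copy()
        for k, (_, mask) in enumerate(perrow_masks):
            d = d + g[n_block + k] * mask
        if qtot:
            scale = np.empty(qtot)
            for k, sl in enumerate(block_slices):
                scale[sl.start:sl.stop] = np.sqrt(g[k])
            U = U0 * scale[None, :]
        else:
            U = U0
        return g, d, U

    def _core(log_gamma):
        """Return (neg2reml, aux dict) for the current variance ratios."""
        g, d, U = _assemble(log_gamma)
        dinv = 1.0 / d
        DiU = U * dinv[:, None]
        A = np.eye(qtot) + U.T @ DiU
        try:
            cA = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return None
        logdetH = 2.0 * np.sum(np.log(np.diag(cA))) + np.sum(np.log(d))

        def Hinv(M):
            M = np.atleast_2d(M.T).T if M.ndim == 1 else M
            DiM = M * dinv[:, None]
            if qtot == 0:
                return DiM
            t = np.linalg.solve(cA.T, np.linalg.solve(cA, DiU.T @ M))
            return DiM - DiU @ t

        HiX = Hinv(X) if p else np.empty((n, 0))
        Hiy = Hinv(y[:, None])[:, 0]
        if p:
            XtHX = X.T @ HiX
            try:
                cX = np.linalg.cholesky(XtHX)
            except np.linalg.LinAlgError:
                return None
            logdetXHX = 2.0 * np.sum(np.log(np.diag(cX)))
            beta = np.linalg.solve(cX.T, np.linalg.solve(cX, X.T @ Hiy))
            r = y - X @ beta
        else:
            logdetXHX = 0.0
            beta = np.empty(0)
            XtHX = np.empty((0, 0))
            r = y
        quad = float(r @ Hinv(r[:, None])[:, 0])
        if quad <= 0:
            quad = 1e-12
        sigma2 = quad / (n - p)
        neg2 = ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                + logdetH + logdetXHX)
        return {"neg2": neg2, "sigma2": sigma2, "beta": beta, "g": g,
                "d": d, "U": U, "Hinv": Hinv, "HiX": HiX,
                "XtHX": XtHX, "r": r}

    def objective(log_gamma):
        out = _core(log_gamma)
        if out is None:
            return 1e12
        return out["neg2"]

    x0 = np.full(n_par, np.log(start_gamma))
    if n_par:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=[(-14.0, 14.0)] * n_par,
                                options={"maxiter": max_iter, "ftol": 1e-12})
        xhat = res.x
        converged = bool(res.success)
        message = str(res.message)
        if not converged:
            res2 = optimize.minimize(objective, xhat, method="Nelder-Mead",
                                     options={"maxiter": 2000, "fatol": 1e-10,
                                              "xatol": 1e-8})
            if res2.fun <= res.fun:
                xhat = res2.x
                converged = bool(res2.success)
                message = str(res2.message)
    else:
        xhat = x0
        converged = True
        message = "no variance ratios to optimize"

    out = _core(xhat)
    if out is None:
        raise RuntimeError("REML likelihood not computable at the optimum")
    sigma2 = out["sigma2"]
    g = out["g"]
    loglik = -0.5 * out["neg2"]

    varcomp = {}
    gammas = {}
    for k, b in enumerate(blocks):
        varcomp[b.name] = float(g[k] * sigma2)
        gammas[b.name] = float(g[k])
    for k, (nm, _) in enumerate(perrow_masks):
        varcomp[nm] = float(g[n_block + k] * sigma2)
        gammas[nm] = float(g[n_block + k])
    varcomp["residual"] = float(sigma2)

    beta = pd.Series(out["beta"], index=list(x_names))
    if p:
        beta_cov = pd.DataFrame(sigma2 * np.linalg.inv(out["XtHX"]),
                                index=list(x_names), columns=list(x_names))
    else:
        beta_cov = pd.DataFrame()

    # BLUPs: u_hat_k = gamma_k K_k Z_k' H^{-1} r
    Hinv = out["Hinv"]
    r = out["r"]
    Hir = Hinv(r[:, None])[:, 0]
    blups = {}
    pevs = {}
    term_levels = {}
    for k, b in enumerate(blocks):
        KZt = (b.K @ b.Z.T) if b.K is not None else b.Z.T
        blups[b.name] = g[k] * (KZt @ Hir)
        term_levels[b.name] = b.levels
        if b.name in compute_pev:
            # PEV = sigma2 * (gamma K - gamma^2 K Z' P_H Z K),
            # P_H = H^{-1} - H^{-1} X (X'H^{-1}X)^{-1} X' H^{-1}
            ZK = KZt.T
            HiZK = Hinv(ZK)
            M = ZK.T @ HiZK
            if p:
                XtHZK = out["HiX"].T @ ZK
                M -= XtHZK.T @ np.linalg.solve(out["XtHX"], XtHZK)
            Kb = b.K if b.K is not None else np.eye(len(b.levels))
            pevs[b.name] = sigma2 * (g[k] * Kb - g[k] ** 2 * M)

    k_par = n_par + 1 + p   # variance parameters + fixed effects
    bic = out["neg2"] + k_par * np.log(n)

    return LmmFit(beta=beta, beta_cov=beta_cov, varcomp=varcomp,
                  sigma2_e=float(sigma2), loglik=float(loglik), bic=float(bic),
                  n=n, p=p, converged=converged, message=message,
                  blups=blups, blup_pev=pevs, term_levels=term_levels,
                  gammas=gammas)


def mean_pairwise_pev_difference(pev: np.ndarray) -> float:
    """Mean over ordered pairs i != j of PEV(u_i - u_j).

    This is the "mean variance of a difference" of BLUPs used by
    difference-based heritability.
    """
    pev = np.asarray(pev, float)
    q = pev.shape[0]
    if q < 2:
        raise ValueError("need at least two levels")
    diag = np.diag(pev)
    total = q * diag.sum() + q * diag.sum() - 2.0 * pev.sum()
    # sum over all ordered pairs (i,j) of pev_ii + pev_jj - 2 pev_ij,
    # minus the i==j terms (which are 2*diag - 2*diag = 0)
    return float(total / (q * (q - 1)))
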