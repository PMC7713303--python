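"""Phylogenetic generalized least squares of traits on habitat.

The regression model is ``y = X b + e`` with ``e ~ N(0, sigma2 * C)`` and
``C`` the Brownian correlation structure: shared root-to-MRCA times scaled
to unit tree height (no extra signal parameter is estimated, matching a
fixed-Brownian covariance).  Estimation whitens both sides with the lower
Cholesky factor of ``C`` and solves the resulting ordinary least-squares
problem, so with ``C = I`` every quantity reduces exactly to classical
OLS / ANOVA / Pearson results.

Post-hoc machinery: nested-model F tests, all-pairs habitat contrasts with a
single-step max-|t| adjustment (the GLS analogue of Tukey's HSD, computed by
seeded Monte-Carlo sampling of the joint contrast distribution; Holm is
available as a deterministic fallback), a compact letter display, a
GLS trait-trait correlation with BM-vs-OU structure selection by AICc, and a
sensitivity summary across posterior tree samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular

from islandtraits.errors import DataError, FitError
from islandtraits.evomodels import aicc, fit_model
from islandtraits.phylo import Phylogeny, tree_matrices

__all__ = [
    "PGLSResult",
    "FTest",
    "ContrastSet",
    "SensitivitySummary",
    "brownian_correlation",
    "design_matrix",
    "fit_pgls",
    "anova_f",
    "pairwise_contrasts",
    "letter_display",
    "phylo_correlation",
    "tree_sensitivity",
]

_LOG2PI = math.log(2.0 * math.pi)


def brownian_correlation(tree: Phylogeny) -> np.ndarray:
    """Shared-time matrix scaled to unit tree height (corBrownian analogue)."""
    S = tree_matrices(tree).S
    return S / tree.height


def design_matrix(habitat, levels=None, covariate=None, interaction=False,
                  covariate_name="covariate") -> pd.DataFrame:
    """Treatment-coded design: intercept + habitat indicators
    [+ covariate + habitat:covariate interaction].

    The reference level is the first of ``levels`` (defaults to the sorted
    unique habitats, so 'continental_island' under the standard labels).
    """
    hab = pd.Series(habitat)
    levels = list(levels) if levels is not None else sorted(hab.unique())
    unknown = set(hab) - set(levels)
    if unknown:
        raise DataError(f"habitat values outside levels: {sorted(unknown)}")
    X = pd.DataFrame({"Intercept": np.ones(len(hab))}, index=hab.index)
    for lev in levels[1:]:
        X[f"habitat[{lev}]"] = (hab == lev).astype(float).values
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        X[covariate_name] = cov
        if interaction:
            for lev in levels[1:]:
                X[f"habitat[{lev}]:{covariate_name}"] = X[f"habitat[{lev}]"] * cov
    return X


@dataclass
class PGLSResult:
    """A fitted GLS regression (whitened-OLS route)."""

    names: list
    beta: np.ndarray
    coef_cov: np.ndarray      # sigma2_unbiased * (X' C^-1 X)^-1
    sigma2: float             # ML residual rate: RSS / n
    RSS: float                # whitened residual sum of squares
    lnL: float
    n: int
    p: int
    # internals kept for nested tests / contrasts
    _Zw: np.ndarray = None    # whitened design
    _yw: np.ndarray = None    # whitened response
    _logdetC: float = 0.0

    @property
    def df_resid(self) -> int:
        return self.n - self.p

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.coef_cov))
        t = self.beta / se
        pv = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        return pd.DataFrame({"coef": self.beta, "se": se, "t": t, "p": pv},
                            index=self.names)


def _whiten(C):
    try:
        Wlow = cholesky(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"correlation matrix not positive definite: {exc}") from None
    return Wlow


def fit_pgls(y, X, tree=None, correlation=None) -> PGLSResult:
    """GLS fit of ``y`` on design ``X`` under a Brownian tree correlation
    (``tree``) or an explicit ``correlation`` matrix.

    The normal equations are never formed with an explicit inverse: both
    sides are whitened with the triangular Cholesky factor of C and the
    coefficients solved by least squares on the whitened system.
    """
    if (tree is None) == (correlation is None):
        raise FitError("pass exactly one of tree= or correlation=")
    C = brownian_correlation(tree) if tree is not None else np.asarray(correlation, float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{j}" for j in range(Xm.shape[1])]
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if yv.shape != (n,) or C.shape != (n, n):
        raise FitError(f"shape mismatch: y {yv.shape}, X {Xm.shape}, C {C.shape}")

    Wlow = _whiten(C)
    yw = solve_triangular(Wlow, yv, lower=True)
    Zw = solve_triangular(Wlow, Xm, lower=True)
    rank = np.linalg.matrix_rank(Zw)
    if rank < p:
        # name the aliased columns: those whose removal keeps the rank
        aliased = []
        for j in range(p):
            keep = [k for k in range(p) if k != j and k not in aliased]
            if np.linalg.matrix_rank(Zw[:, keep]) == rank:
                aliased.append(j)
                if p - len(aliased) == rank:
                    break
        raise FitError(f"rank-deficient design; aliased columns: "
                       f"{[names[j] for j in aliased]}")
    beta, _, _, _ = np.linalg.lstsq(Zw, yw, rcond=None)
    resid = yw - Zw @ beta
    RSS = float(resid @ resid)
    sigma2_ml = RSS / n
    logdetC = 2.0 * float(np.log(np.diag(Wlow)).sum())
    lnL = (-0.5 * (n * (_LOG2PI + math.log(sigma2_ml)) + logdetC + n)
           if sigma2_ml > 0 else math.inf)
    s2_unbiased = RSS / (n - p) if n > p else np.nan
    XtX_inv = np.linalg.inv(Zw.T @ Zw)  # p x p; small
    return PGLSResult(names=names, beta=beta, coef_cov=s2_unbiased * XtX_inv,
                      sigma2=sigma2_ml, RSS=RSS, lnL=float(lnL), n=n, p=p,
                      _Zw=Zw, _yw=yw, _logdetC=logdetC)


@dataclass(frozen=True)
class FTest:
    F: float
    df1: int
    df2: int
    p_value: float

    def __str__(self):
        return f"F_{self.df1},{self.df2} = {self.F:.4g}, p = {self.p_value:.4g}"


def anova_f(full: PGLSResult, reduced: PGLSResult) -> FTest:
    """F test of a reduced design nested in a full design (same y, same C)."""
    if full.n != reduced.n:
        raise FitError("full and reduced models use different n")
    if reduced.p >= full.p:
        raise FitError("reduced model must have fewer columns than the full model")
    # nesting check on the whitened designs: reduced columns must lie in the
    # column space of the full design
    proj, _, _, _ = np.linalg.lstsq(full._Zw, reduced._Zw, rcond=None)
    if not np.allclose(full._Zw @ proj, reduced._Zw, atol=1e-8 * max(1.0, np.abs(reduced._Zw).max())):
        raise FitError("designs are not nested")
    df1 = full.p - reduced.p
    df2 = full.n - full.p
    num = (reduced.RSS - full.RSS) / df1
    den = full.RSS / df2
    if den <= 0:
        return FTest(F=math.inf if num > 0 else 0.0, df1=df1, df2=df2,
                     p_value=0.0 if num > 0 else 1.0)
    F = max(num / den, 0.0)
    return FTest(F=float(F), df1=df1, df2=df2,
                 p_value=float(stats.f.sf(F, df1, df2)))


# ---------------------------------------------------------------------------
# pairwise contrasts


@dataclass(frozen=True)
class ContrastSet:
    """All-pairs level contrasts with multiplicity-adjusted p-values."""

    pairs: list           # (level_a, level_b)
    estimate: np.ndarray  # mean(a) - mean(b)
    se: np.ndarray
    statistic: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    method: str
    letters: dict         # level -> letter string
    alpha: float


def letter_display(levels, sig_pairs, order_stat=None) -> dict:
    """Compact letter display: levels sharing a letter are not significantly
    different.  Letters label the maximal cliques of the non-significance
    graph, ordered deterministically (by ``order_stat`` when given, else by
    level order)."""
    levels = list(levels)
    k = len(levels)
    sig = {frozenset(p) for p in sig_pairs}
    # maximal subsets with no significant pair inside (k is tiny: enumerate)
    cliques = []
    for mask in range(1, 1 << k):
        members = [levels[i] for i in range(k) if mask >> i & 1]
        if any(frozenset(p) in sig for p in combinations(members, 2)):
            continue
        cliques.append(set(members))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    key = (lambda c: min(order_stat[l] for l in c)) if order_stat else \
          (lambda c: min(levels.index(l) for l in c))
    maximal.sort(key=key)
    letters = {l: "" for l in levels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", maximal):
        for l in levels:
            if l in clique:
                letters[l] += letter
    return letters


def pairwise_contrasts(fit: PGLSResult, levels, method: str = "mc",
                       alpha: float = 0.05, n_draws: int = 50_000,
                       seed: int = 0) -> ContrastSet:
    """All pairwise differences between factor levels of a treatment-coded
    fit (columns ``habitat[<level>]``; the first level is the reference).

    ``method="mc"``: single-step max-|t| adjustment sampled from the joint
    t distribution of the contrasts (seeded; the GLS analogue of Tukey's
    HSD).  ``method="holm"``: deterministic Holm step-down on the raw
    two-sided t p-values.
    """
    levels = list(levels)
    cols = {lev: f"habitat[{lev}]" for lev in levels[1:]}
    missing = [c for c in cols.values() if c not in fit.names]
    if missing:
        raise FitError(f"fit lacks factor columns: {missing}")
    idx = {lev: fit.names.index(col) for lev, col in cols.items()}
    p = fit.p

    def cvec(lev):
        v = np.zeros(p)
        if lev in idx:
            v[idx[lev]] = 1.0
        return v

    pairs = list(combinations(levels, 2))
    Cmat = np.array([cvec(a) - cvec(b) for a, b in pairs])
    est = Cmat @ fit.beta
    cov = Cmat @ fit.coef_cov @ Cmat.T
    se = np.sqrt(np.diag(cov))
    if np.any(se == 0):
        raise FitError("zero-variance contrast (factor level without data?)")
    tstat = est / se
    df = fit.df_resid
    p_raw = 2.0 * stats.t.sf(np.abs(tstat), df)

    if method == "mc":
        R = cov / np.outer(se, se)
        rng = np.random.default_rng(seed)
        # multivariate t draws: N(0, R) scaled by sqrt(df / chi2_df)
        # contrast set is linearly dependent (k levels -> k(k-1)/2 pairs), so
        # the correlation matrix is only PSD; svd factorization handles that
        Z = rng.multivariate_normal(np.zeros(len(pairs)), R, size=n_draws,
                                    method="svd")
        s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
        maxabs = np.abs(Z / s[:, None]).max(axis=1)
        p_adj = np.array([(maxabs >= abs(t)).mean() for t in tstat])
        p_adj = np.maximum(p_adj, p_raw)  # single-step adj can never undercut raw
    elif method == "holm":
        order = np.argsort(p_raw)
        m = len(p_raw)
        p_adj = np.empty(m)
        running = 0.0
        for rank, j in enumerate(order):
            running = max(running, (m - rank) * p_raw[j])
            p_adj[j] = min(1.0, running)
    else:
        raise FitError(f"unknown adjustment method {method!r}")

    sig_pairs = [pr for pr, pa in zip(pairs, p_adj) if pa < alpha]
    # order letters by fitted group means (reference level has mean = intercept)
    means = {}
    for lev in levels:
        v = cvec(lev)
        if "Intercept" in fit.names:
            v[fit.names.index("Intercept")] = 1.0
        means[lev] = float(v @ fit.beta)
    letters = letter_display(levels, sig_pairs, order_stat=means)
    return ContrastSet(pairs=pairs, estimate=est, se=se, statistic=tstat,
                       p_raw=p_raw, p_adjusted=p_adj, method=method,
                       letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# trait-trait correlation


def phylo_correlation(x, y, tree: Phylogeny, structure: str = "auto"):
    """GLS correlation between two traits on the same tips.

    ``structure``: ``"BM"``, ``"OU"``, or ``"auto"`` — for auto, each trait
    is fitted under both models and the structure with the smaller summed
    AICc is used; under OU the correlation matrix uses the mean of the two
    per-trait maximum-likelihood alpha values.

    Returns a dict with ``r``, ``df`` (= n - 2), ``p`` (t test), the chosen
    structure, and the GLS slope of y on x with its standard error.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = xv.size
    if n < 4:
        raise FitError("phylo_correlation needs n >= 4")
    if yv.size != n or n != tree.n_tips:
        raise FitError("x, y must align with the tree tips")

    chosen = structure
    alpha_hat = 0.0
    if structure == "auto":
        tot = {"BM": 0.0, "OU": 0.0}
        alphas = []
        for v in (xv, yv):
            for m in ("BM", "OU"):
                f = fit_model(m, tree, v)
                tot[m] += f.AICc
                if m == "OU":
                    alphas.append(f.params["alpha"])
        chosen = "OU" if tot["OU"] < tot["BM"] else "BM"
        alpha_hat = float(np.mean(alphas))
    elif structure == "OU":
        alphas = [fit_model("OU", tree, v).params["alpha"] for v in (xv, yv)]
        alpha_hat = float(np.mean(alphas))
    elif structure != "BM":
        raise FitError(f"unknown structure {structure!r}")

    if chosen == "BM":
        C = brownian_correlation(tree)
    else:
        M = tree_matrices(tree)
        V = (-np.expm1(-2.0 * alpha_hat * M.S) / (2.0 * alpha_hat)) * \
            np.exp(-alpha_hat * M.D) if alpha_hat > 0 else M.S
        C = V / V.max()

    Wlow = _whiten(C)
    xw = solve_triangular(Wlow, xv, lower=True)
    yw = solve_triangular(Wlow, yv, lower=True)
    onew = solve_triangular(Wlow, np.ones(n), lower=True)
    # GLS centering: remove the C-weighted mean
    def center(v):
        mu = float(onew @ v) / float(onew @ onew)
        return v - mu * onew, mu
    xc, _ = center(xw)
    yc, _ = center(yw)
    sxx, syy, sxy = float(xc @ xc), float(yc @ yc), float(xc @ yc)
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    tval = r * math.sqrt(df / max(1.0 - r * r, 1e-300))
    pval = 2.0 * stats.t.sf(abs(tval), df)
    slope = sxy / sxx
    resid = yc - slope * xc
    slope_se = math.sqrt(float(resid @ resid) / df / sxx)
    return {"r": float(r), "df": df, "p": float(pval), "structure": chosen,
            "alpha": alpha_hat, "slope": float(slope), "slope_se": slope_se,
            "n": n}


# ---------------------------------------------------------------------------
# sensitivity across posterior trees


@dataclass(frozen=True)
class SensitivitySummary:
    coef_stats: pd.DataFrame    # per-coefficient mean, sd, min, max
    prop_significant: float     # trees with term p < alpha
    sensitive: bool             # significance flips across trees
    n_trees: int
    n_failed: int
    per_tree_p: np.ndarray


def tree_sensitivity(trees, y, X_full, X_reduced, alpha: float = 0.05) -> SensitivitySummary:
    """Refit a pGLS model across a posterior tree sample.

    Each tree supplies its own Brownian correlation; the response and the
    designs are fixed (rows aligned to the common tip order).  Summarizes
    per-coefficient spread and the proportion of trees where the
    full-vs-reduced F test is significant at ``alpha``.
    """
    if len(trees) < 2:
        raise FitError("need >= 2 trees for a sensitivity analysis")
    betas, pvals, failures = [], [], 0
    names = list(X_full.columns) if isinstance(X_full, pd.DataFrame) else None
    for t in trees:
        try:
            full = fit_pgls(y, X_full, tree=t)
            red = fit_pgls(y, X_reduced, tree=t)
            ft = anova_f(full, red)
        except FitError:
            failures += 1
            continue
        betas.append(full.beta)
        pvals.append(ft.p_value)
    if not betas:
        raise FitError("pGLS failed on every tree")
    B = np.array(betas)
    P = np.array(pvals)
    stats_df = pd.DataFrame({
        "mean": B.mean(axis=0),
        "sd": B.std(axis=0, ddof=1) if len(B) > 1 else np.zeros(B.shape[1]),
        "min": B.min(axis=0),
        "max": B.max(axis=0),
    }, index=names or [f"b{j}" for j in range(B.shape[1])])
    prop = float((P < alpha).mean())
    return SensitivitySummary(coef_stats=stats_df, prop_significant=prop,
                              sensitive=0.0 < prop < 1.0,
                              n_trees=len(B), n_failed=failures,
                              per_tree_p=P)
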