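"""Maximum-likelihood trait-evolution models and AICc model selection.

Four single-trait models on a time-calibrated tree:

* **BM** — Brownian motion; tip vector is multivariate normal with mean
  ``z0`` and covariance ``sigma2 * S`` (S = shared root-to-MRCA time).
* **OU** — Ornstein-Uhlenbeck with the root fixed at the optimum (one mean
  parameter ``z0``); ``Cov[i,j] = sigma2/(2 alpha) * (1 - exp(-2 alpha S_ij))
  * exp(-alpha D_ij)``, which reduces analytically to BM as ``alpha -> 0``.
* **EB** — early burst: BM whose rate decays as ``exp(a * t)`` (a <= 0); a
  branch spanning root-times ``[t1, t2]`` gets effective length
  ``(exp(a t2) - exp(a t1)) / a``.
* **WN** — white noise: i.i.d. normal tips, no phylogenetic structure.

Parameter counts follow the non-stationary-OU convention: 2 for BM
(sigma2, z0) and WN (mu, sigma2), 3 for OU (sigma2, alpha, z0) and EB
(sigma2, a, z0).

Every likelihood is available through two independent routes — a dense
multivariate-normal evaluation built from the covariance matrix and an
O(n) contrast (pruning) evaluation on a depth-rescaled tree — which must
agree; the test-suite holds them to 1e-8.  Fitting profiles ``z0``/``mu``
and ``sigma2`` analytically and optimizes the single shape parameter of
OU/EB by a seeded multi-start grid refined with bounded scalar search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize_scalar

from islandtraits.errors import FitError, NotUltrametricError
from islandtraits.phylo import (
    DEFAULT_ULTRAMETRIC_RTOL,
    Phylogeny,
    extract_clade,
    normalize_label,
    tree_matrices,
    validate_ultrametric,
)

__all__ = [
    "MODELS",
    "ModelFit",
    "ModelComparison",
    "MultiTreeComparison",
    "align_trait",
    "model_loglik",
    "fit_model",
    "model_table",
    "fit_across_trees",
    "aicc",
    "akaike_weights",
]

MODELS = ("BM", "OU", "EB", "WN")

#: parameters counted for AICc, per model
K_PARAMS = {"BM": 2, "WN": 2, "OU": 3, "EB": 3}

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data alignment


def align_trait(tree: Phylogeny, x):
    """Prune ``tree`` to the tips with data and return ``(tree, values)``.

    ``x`` may be a mapping/Series keyed by (normalized) tip label, or an
    array already aligned to ``tree.tip_labels``.  NaNs count as missing.
    """
    if hasattr(x, "keys"):
        lut = {normalize_label(str(k)): float(v) for k, v in dict(x).items()}
        have = [
            lab
            for lab in tree.tip_labels
            if normalize_label(lab) in lut and np.isfinite(lut[normalize_label(lab)])
        ]
        if len(have) < tree.n_tips:
            if len(have) < 2:
                raise FitError(f"only {len(have)} tips have trait data")
            tree = extract_clade(tree, have)
        vals = np.array([lut[normalize_label(lab)] for lab in tree.tip_labels])
        return tree, vals
    arr = np.asarray(x, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise FitError(
            f"trait array length {arr.size} does not match {tree.n_tips} tips"
        )
    if np.isnan(arr).any():
        have = [lab for lab, v in zip(tree.tip_labels, arr) if np.isfinite(v)]
        return align_trait(tree, dict(zip(tree.tip_labels, arr)))
    return tree, arr


def _require_ultrametric(tree, model, force):
    if model in ("OU", "EB") and not force:
        ok, dev = validate_ultrametric(tree, DEFAULT_ULTRAMETRIC_RTOL)
        if not ok:
            raise NotUltrametricError(
                f"{model} requires an ultrametric tree (max relative depth "
                f"deviation {dev:.3g}); pass force=True to override"
            )


# ---------------------------------------------------------------------------
# covariance construction (dense route)


def _check_params(model, params):
    s2 = params.get("sigma2")
    if s2 is None or s2 < 0:
        raise FitError(f"{model}: sigma2 must be >= 0, got {s2}")
    if model == "OU":
        if params.get("alpha", 0.0) < 0:
            raise FitError(f"OU: alpha must be >= 0, got {params.get('alpha')}")
    if model == "EB":
        if params.get("a", 0.0) > 0:
            raise FitError(f"EB: exponent a must be <= 0, got {params.get('a')}")


def _base_cov(model, S, D, shape):
    """Unit-rate covariance V0 such that Cov = sigma2 * V0."""
    if model == "BM":
        return S
    if model == "WN":
        return np.eye(S.shape[0])
    if model == "OU":
        alpha = shape
        if alpha <= 0:
            return S
        # -expm1(-2 a S)/(2 a) stays accurate as alpha -> 0
        return (-np.expm1(-2.0 * alpha * S) / (2.0 * alpha)) * np.exp(-alpha * D)
    if model == "EB":
        a = shape
        if a == 0:
            return S
        return np.expm1(a * S) / a
    raise FitError(f"unknown model {model!r}")


def _shape_of(model, params):
    if model == "OU":
        return float(params.get("alpha", 0.0))
    if model == "EB":
        return float(params.get("a", 0.0))
    return 0.0


def _mean_of(model, params):
    return float(params["mu"] if model == "WN" else params["z0"])


def _mvn_loglik(resid, V):
    n = resid.size
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"covariance not positive definite: {exc}") from None
    logdet = 2.0 * np.log(np.diag(c)).sum()
    quad = float(resid @ cho_solve((c, low), resid))
    return -0.5 * (n * _LOG2PI + logdet + quad)


def _dense_loglik(model, tree, x, params):
    M = tree_matrices(tree)
    s2 = float(params["sigma2"])
    V0 = _base_cov(model, M.S, M.D, _shape_of(model, params))
    resid = x - _mean_of(model, params)
    if s2 == 0.0:
        return math.inf if np.allclose(resid, 0.0) else -math.inf
    return _mvn_loglik(resid, s2 * V0)


# ---------------------------------------------------------------------------
# pruning route: BM contrasts on a depth-rescaled tree


def _rescaled_lengths(model, tree, shape):
    """Branch lengths after the model's monotone time warp g(depth)."""
    if model == "BM" or shape == 0.0:
        return tree.length
    depths = tree.depths()
    if model == "EB":
        g = np.expm1(shape * depths) / shape
    elif model == "OU":
        T = tree.height
        # ultrametric identity: Cov = sigma2 * exp(-2 a T) (exp(2 a S)-1)/(2a)
        g = np.exp(-2.0 * shape * T) * np.expm1(2.0 * shape * depths) / (2.0 * shape)
    else:
        raise FitError(f"no rescaling for model {model!r}")
    out = np.zeros_like(tree.length)
    for v in range(tree.n_nodes - 1):
        out[v] = g[v] - g[tree.parent[v]]
    return out


def _bm_pruning_loglik(tree: Phylogeny, lengths, x, sigma2, z0):
    """Felsenstein contrast likelihood of BM(sigma2, root mean z0)."""
    if sigma2 == 0.0:
        return math.inf if np.allclose(x - z0, 0.0) else -math.inf
    pos_of = {int(t): i for i, t in enumerate(tree.tip_ids)}
    mu = np.zeros(tree.n_nodes)
    vex = np.zeros(tree.n_nodes)  # variance accumulated above the node value
    lnL = 0.0
    for v in range(tree.n_nodes):
        ch = tree.children[v]
        if not ch:
            mu[v] = x[pos_of[v]]
            vex[v] = 0.0
            continue
        m, w = mu[ch[0]], vex[ch[0]] + lengths[ch[0]]
        for c in ch[1:]:
            mc, wc = mu[c], vex[c] + lengths[c]
            tot = w + wc
            diff = m - mc
            if tot <= 0.0:
                if abs(diff) > 0.0:
                    return -math.inf
            else:
                lnL -= 0.5 * (_LOG2PI + math.log(sigma2 * tot) + diff * diff / (sigma2 * tot))
                m = (wc * m + w * mc) / tot
                w = w * wc / tot
        mu[v], vex[v] = m, w
    vroot = vex[tree.root]
    d = mu[tree.root] - z0
    if vroot <= 0.0:
        if abs(d) > 0.0:
            return -math.inf
    else:
        lnL -= 0.5 * (_LOG2PI + math.log(sigma2 * vroot) + d * d / (sigma2 * vroot))
    return lnL


def model_loglik(model, tree, x, params, method="pruning", force=False):
    """Log-likelihood of ``x`` (tip -> value) under ``model`` with ``params``.

    ``method`` selects the dense multivariate-normal route (``"dense"``) or
    the O(n) contrast route (``"pruning"``); the two agree to numerical
    precision and serve as mutual cross-checks.
    """
    if model not in MODELS:
        raise FitError(f"unknown model {model!r}; choose from {MODELS}")
    _check_params(model, params)
    tree, xv = align_trait(tree, x)
    _require_ultrametric(tree, model, force)
    if method == "dense":
        return _dense_loglik(model, tree, xv, params)
    if method != "pruning":
        raise FitError(f"unknown method {method!r}")
    s2 = float(params["sigma2"])
    if model == "WN":
        mu = _mean_of(model, params)
        if s2 == 0.0:
            return math.inf if np.allclose(xv - mu, 0.0) else -math.inf
        return float(
            -0.5 * (xv.size * (_LOG2PI + math.log(s2)) + ((xv - mu) ** 2).sum() / s2)
        )
    lengths = _rescaled_lengths(model, tree, _shape_of(model, params))
    return _bm_pruning_loglik(tree, lengths, xv, s2, _mean_of(model, params))


# ---------------------------------------------------------------------------
# fitting


def aicc(lnL: float, k: int, n: int) -> float:
    """Sample-size-corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise FitError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from AICc values (max-subtraction for stability)."""
    a = np.asarray(aicc_values, dtype=float)
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


@dataclass(frozen=True)
class ModelFit:
    """One fitted trait-evolution model."""

    model: str
    params: dict
    lnL: float
    k: int
    n: int
    AICc: float

    def as_dict(self):
        d = {"model": self.model, "lnL": self.lnL, "k": self.k, "n": self.n,
             "AICc": self.AICc}
        d.update({f"param_{k}": v for k, v in self.params.items()})
        return d


def _profile_given_V0(V0, x):
    """GLS-profile (mean, sigma2, lnL) for x ~ N(m 1, sigma2 V0)."""
    n = x.size
    try:
        c, low = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"covariance not positive definite: {exc}") from None
    one = np.ones(n)
    Vi1 = cho_solve((c, low), one)
    m = float(Vi1 @ x) / float(Vi1 @ one)
    r = x - m
    quad = float(r @ cho_solve((c, low), r))
    logdet = 2.0 * np.log(np.diag(c)).sum()
    s2 = quad / n
    if s2 <= 0.0:
        return m, 0.0, math.inf
    lnL = -0.5 * (n * (_LOG2PI + math.log(s2)) + logdet + n)
    return m, s2, lnL


def fit_model(model, tree, x, force=False, n_starts: int = 5) -> ModelFit:
    """ML fit of one model; mean and rate profiled in closed form, the OU/EB
    shape parameter found by a log/linear grid of ``n_starts`` starting points
    refined with bounded scalar minimization."""
    tree, xv = align_trait(tree, x)
    n = xv.size
    if n < 4:
        raise FitError(f"need >= 4 tips with data to fit {model}, got {n}")
    _require_ultrametric(tree, model, force)
    M = tree_matrices(tree)
    T = tree.height

    if model == "WN":
        mu = float(xv.mean())
        s2 = float(((xv - mu) ** 2).mean())
        lnL = (
            math.inf
            if s2 == 0.0
            else -0.5 * n * (_LOG2PI + math.log(s2) + 1.0)
        )
        params = {"mu": mu, "sigma2": s2}
    elif model == "BM":
        m, s2, lnL = _profile_given_V0(M.S, xv)
        params = {"z0": m, "sigma2": s2}
    else:
        if model == "OU":
            lo, hi = 1e-8 / T, 50.0 / T
            grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_starts))
            key = "alpha"
        else:  # EB
            lo, hi = math.log(1e-5) / T, 0.0
            grid = np.linspace(lo, hi, n_starts)
            key = "a"

        def neg_prof(shape):
            V0 = _base_cov(model, M.S, M.D, float(shape))
            try:
                _, _, lnL = _profile_given_V0(V0, xv)
            except FitError:
                return math.inf
            return -lnL if math.isfinite(lnL) else -1e300

        best_shape, best_val = None, math.inf
        vals = [neg_prof(g) for g in grid]
        order = np.argsort(vals)
        for j in order[:3]:  # refine around the best grid starts
            a = grid[max(0, j - 1)]
            b = grid[min(len(grid) - 1, j + 1)]
            if a == b:
                a, b = lo, hi
            res = minimize_scalar(neg_prof, bounds=(min(a, b), max(a, b)),
                                  method="bounded",
                                  options={"xatol": 1e-10 * (hi - lo) + 1e-14})
            for cand, cval in ((float(res.x), float(res.fun)), (float(grid[j]), float(vals[j]))):
                if cval < best_val:
                    best_shape, best_val = cand, cval
        if best_shape is None or not math.isfinite(best_val):
            raise FitError(f"{model} optimization failed; best objective {best_val}")
        V0 = _base_cov(model, M.S, M.D, best_shape)
        m, s2, lnL = _profile_given_V0(V0, xv)
        params = {"z0": m, "sigma2": s2, key: best_shape}

    k = K_PARAMS[model]
    return ModelFit(model=model, params=params, lnL=float(lnL), k=k, n=n,
                    AICc=aicc(lnL, k, n) if math.isfinite(lnL) else -math.inf)


# ---------------------------------------------------------------------------
# model comparison


_TIE_ORDER = {m: i for i, m in enumerate(("BM", "WN", "OU", "EB"))}


@dataclass(frozen=True)
class ModelComparison:
    """AICc comparison across the four models on one tree."""

    fits: dict            # model -> ModelFit
    delta_aicc: dict      # model -> AICc - min AICc
    weights: dict         # model -> Akaike weight
    best: str

    def to_rows(self):
        """Rows sorted by delta AICc (Table-style output)."""
        rows = []
        for m in sorted(self.fits, key=lambda m: (self.delta_aicc[m],
                                                  _TIE_ORDER[m])):
            f = self.fits[m]
            rows.append({
                "model": m,
                "delta_AICc": self.delta_aicc[m],
                "lnL": f.lnL,
                "k": f.k,
                "AICc": f.AICc,
                "weight": self.weights[m],
            })
        return rows


def compare_fits(fits: dict) -> ModelComparison:
    """Build a :class:`ModelComparison` from per-model fits."""
    models = list(fits)
    a = np.array([fits[m].AICc for m in models])
    w = akaike_weights(a)
    amin = a.min()
    delta = {m: float(fits[m].AICc - amin) for m in models}
    # tie-break: smallest AICc, then fewer parameters, then fixed model order
    best = min(models, key=lambda m: (fits[m].AICc, fits[m].k, _TIE_ORDER[m]))
    return ModelComparison(fits=fits,
                           delta_aicc=delta,
                           weights={m: float(x) for m, x in zip(models, w)},
                           best=best)


def model_table(tree, x, models=MODELS, force=False) -> ModelComparison:
    """Fit every model in ``models`` and compare by AICc."""
    fits = {m: fit_model(m, tree, x, force=force) for m in models}
    return compare_fits(fits)


@dataclass(frozen=True)
class MultiTreeComparison:
    """Mean Akaike weight and its standard error across a tree sample."""

    models: tuple
    mean_weight: dict
    se_weight: dict
    per_tree: list        # list of ModelComparison (successful trees)
    n_trees: int
    n_failed: int


def fit_across_trees(trees, x, models=MODELS, force=False) -> MultiTreeComparison:
    """Fit the models on every tree (each pruned to the tips with data) and
    summarize Akaike weights as mean +/- SE over trees."""
    if len(trees) < 2:
        raise FitError("need >= 2 trees for a multi-tree comparison")
    per_tree, failures = [], []
    for i, t in enumerate(trees):
        try:
            per_tree.append(model_table(t, x, models=models, force=force))
        except FitError as exc:
            failures.append((i, str(exc)))
    if not per_tree:
        raise FitError("model fitting failed on every tree")
    if failures and len(per_tree) < 0.9 * len(trees):
        raise FitError(
            f"model fitting failed on {len(failures)}/{len(trees)} trees"
        )
    W = np.array([[c.weights[m] for m in models] for c in per_tree])
    mean = W.mean(axis=0)
    se = (W.std(axis=0, ddof=1) / math.sqrt(W.shape[0])) if W.shape[0] > 1 else np.zeros(len(models))
    return MultiTreeComparison(
        models=tuple(models),
        mean_weight={m: float(v) for m, v in zip(models, mean)},
        se_weight={m: float(v) for m, v in zip(models, se)},
        per_tree=per_tree,
        n_trees=len(per_tree),
        n_failed=len(failures),
    )
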