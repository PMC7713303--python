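"""Phylogenetic ridge regression rates and habitat rate-shift tests.

The tip value of a trait is modeled as the root state plus the sum, along
the root-to-tip path, of (branch length x branch rate):

    x = m 1 + L beta + error,

with ``L`` the tips-by-edges path matrix.  Because there are always more
edges than tips the system is underdetermined, so the rates are the ridge
solution minimizing ``||x - m 1 - L beta||^2 + lambda ||beta||^2`` (the root
state ``m`` is not penalized), solved through the augmented normal
equations.  Ancestral states follow by accumulating length x rate down each
path.  The penalty is chosen by generalized cross-validation (GCV) on a
log-spaced grid refined by golden-section search — deterministic, smallest
lambda on ties.

The habitat shift test compares standardized absolute terminal-edge rates of
one habitat state against all remaining tips (and state pairs against each
other) by label permutation.  With ``p`` the fraction of permutations whose
rate difference falls at or below the observed one, ``p > 0.975`` flags
increased and ``p < 0.025`` decreased rates for that state; anything between
is no difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from islandtraits.errors import FitError
from islandtraits.phylo import Phylogeny, normalize_label, tree_matrices

__all__ = [
    "RidgeFit",
    "ShiftTest",
    "ridge_rates",
    "optimize_lambda",
    "search_shift_state",
    "tip_rates",
]


@dataclass(frozen=True)
class RidgeFit:
    """Ridge-regression rates: one signed rate per edge plus the root state.

    ``rates[e]`` is indexed by edge id = postorder node id of the edge's
    child (matching :class:`~islandtraits.phylo.TreeMatrices`);
    ``ancestral_states`` covers every node (postorder ids).
    """

    lam: float
    root_state: float
    rates: np.ndarray
    ancestral_states: np.ndarray
    fitted_tips: np.ndarray
    tip_labels: tuple


def ridge_rates(tree: Phylogeny, x, lam: float) -> RidgeFit:
    """Solve the penalized path regression at penalty ``lam`` (> 0 required:
    with more edges than tips the unpenalized system is underdetermined)."""
    if lam < 0:
        raise FitError("lambda must be >= 0")
    if lam == 0:
        raise FitError("lambda = 0 is underdetermined (more edges than tips); "
                       "use optimize_lambda or pass lambda > 0")
    xv = _tip_vector(tree, x)
    M = tree_matrices(tree)
    n, E = M.L.shape
    A = np.column_stack([np.ones(n), M.L])
    G = A.T @ A
    G[1:, 1:] += lam * np.eye(E)
    theta = np.linalg.solve(G, A.T @ xv)
    m, beta = float(theta[0]), theta[1:]

    anc = np.zeros(tree.n_nodes)
    anc[tree.root] = m
    for v in range(tree.n_nodes - 2, -1, -1):
        anc[v] = anc[tree.parent[v]] + tree.length[v] * beta[v]
    fitted = anc[tree.tip_ids]
    return RidgeFit(lam=float(lam), root_state=m, rates=beta,
                    ancestral_states=anc, fitted_tips=fitted,
                    tip_labels=tree.tip_labels)


def _tip_vector(tree, x):
    if hasattr(x, "keys"):
        lut = {normalize_label(str(k)): float(v) for k, v in dict(x).items()}
        try:
            return np.array([lut[normalize_label(l)] for l in tree.tip_labels])
        except KeyError as exc:
            raise FitError(f"trait missing for tip {exc}") from None
    xv = np.asarray(x, dtype=float)
    if xv.shape != (tree.n_tips,):
        raise FitError(f"trait vector length {xv.size} != {tree.n_tips} tips")
    if np.isnan(xv).any():
        raise FitError("ridge regression requires a value for every tip")
    return xv


def optimize_lambda(tree: Phylogeny, x, bounds=None, n_grid: int = 25) -> float:
    """GCV-optimal ridge penalty.

    The intercept is profiled out by centering, the centered path matrix is
    SVD-factored once, and GCV(lambda) = n ||r||^2 / (n - 1 - tr H)^2 is
    evaluated on a log grid over ``bounds`` (default: 1e-6..1e2 times the
    largest squared singular value) and refined by golden-section search on
    log(lambda).  Deterministic; exact ties go to the smallest lambda.  A
    flat objective (e.g. a constant trait) returns the grid minimum with a
    warning.
    """
    if tree.n_tips < 4:
        raise FitError("optimize_lambda needs >= 4 tips")
    xv = _tip_vector(tree, x)
    L = tree_matrices(tree).L
    n = xv.size
    Lc = L - L.mean(axis=0)
    xc = xv - xv.mean()
    U, s, _ = np.linalg.svd(Lc, full_matrices=False)
    s2 = s ** 2
    u = U.T @ xc
    xnorm2 = float(xc @ xc)

    if bounds is None:
        top = float(s2.max()) if s2.size and s2.max() > 0 else 1.0
        bounds = (1e-6 * top, 1e2 * top)
    lo, hi = bounds

    def gcv(lam):
        shrink = s2 / (s2 + lam)
        # ||r||^2 = ||x_c||^2 - 2 sum shrink u^2 + sum shrink^2 u^2
        rss = xnorm2 - float(((2.0 - shrink) * shrink) @ (u ** 2))
        df = 1.0 + float(shrink.sum())
        denom = n - df
        if denom <= 0:
            return math.inf
        return n * max(rss, 0.0) / denom ** 2

    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
    vals = np.array([gcv(g) for g in grid])
    if np.allclose(vals, vals[0], rtol=1e-12, atol=1e-300):
        warnings.warn("flat GCV objective; returning the smallest grid lambda")
        return float(grid[0])
    j = int(np.argmin(vals))  # argmin returns the first (smallest lambda) tie
    a = math.log(grid[max(0, j - 1)])
    b = math.log(grid[min(n_grid - 1, j + 1)])
    # golden-section on log(lambda)
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = gcv(math.exp(c)), gcv(math.exp(d))
    for _ in range(60):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = gcv(math.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = gcv(math.exp(d))
    lam = math.exp((a + b) / 2.0)
    return float(min((gcv(lam), lam), (vals[j], grid[j]))[1])


# ---------------------------------------------------------------------------
# habitat shift test


def tip_rates(tree: Phylogeny, fit: RidgeFit, mode: str = "terminal") -> np.ndarray:
    """Per-tip rate statistic: absolute value of the standardized
    terminal-edge rate (``mode="terminal"``, default) or of the standardized
    mean rate along the root-to-tip path (``mode="path"``)."""
    if mode == "terminal":
        raw = fit.rates[tree.tip_ids]
    elif mode == "path":
        M = tree_matrices(tree)
        onpath = M.L > 0
        raw = (onpath @ fit.rates) / onpath.sum(axis=1)
    else:
        raise FitError(f"unknown tip-rate mode {mode!r}")
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return np.abs((raw - raw.mean()) / sd)


@dataclass(frozen=True)
class ShiftTest:
    """Permutation test of per-state rate differences.

    ``state_results[s] = (delta, p, verdict)`` with delta the mean
    standardized absolute tip rate of state s minus that of all other tips;
    ``pairwise[(a, b)]`` the same restricted to tips of states a and b.
    Verdicts follow the 0.025/0.975 two-tail rule: ``"increase"``,
    ``"decrease"``, or ``"none"``.
    """

    state_results: dict
    pairwise: dict
    n_perm: int
    seed: int
    excluded_states: tuple


def _verdict(p):
    if p > 0.975:
        return "increase"
    if p < 0.025:
        return "decrease"
    return "none"


def _perm_test(rates, mask, n_perm, rng):
    """p = fraction of label permutations with permuted delta <= observed."""
    n_s = int(mask.sum())
    obs = rates[mask].mean() - rates[~mask].mean()
    n = rates.size
    # permuting labels == choosing a random subset of size n_s for the state
    picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_s]
    in_mean = rates[picks].mean(axis=1)
    tot = rates.sum()
    out_mean = (tot - in_mean * n_s) / (n - n_s)
    perm = in_mean - out_mean
    return float(obs), float((perm <= obs).mean())


def search_shift_state(tree: Phylogeny, fit: RidgeFit, states,
                       n_perm: int = 1000, seed: int = 0,
                       mode: str = "terminal") -> ShiftTest:
    """Test whether rates of each habitat state differ from the rest of the
    phylogeny, plus all pairwise state comparisons.

    ``states`` maps tip label -> state; every tip of the (already pruned,
    widespread-free) tree must be covered.  States with fewer than 2 tips
    are excluded with a warning.  Seeded and reproducible; p-values are
    invariant to tip ordering.
    """
    lut = {normalize_label(str(k)): v for k, v in dict(states).items()}
    try:
        lab_states = np.array([lut[normalize_label(l)] for l in tree.tip_labels])
    except KeyError as exc:
        raise FitError(f"state missing for tip {exc}") from None
    rates = tip_rates(tree, fit, mode=mode)

    # sort tips by normalized label so results do not depend on tip order
    order = np.argsort([normalize_label(l) for l in tree.tip_labels])
    rates = rates[order]
    lab_states = lab_states[order]

    uniq, counts = np.unique(lab_states, return_counts=True)
    excluded = tuple(s for s, c in zip(uniq, counts) if c < 2)
    if excluded:
        warnings.warn(f"states with < 2 tips excluded: {excluded}")
    keep_states = [s for s in uniq if s not in excluded]
    if len(keep_states) < 2:
        raise FitError("need >= 2 states with >= 2 tips each")

    rng = np.random.default_rng(seed)
    state_results = {}
    for s in keep_states:
        delta, p = _perm_test(rates, lab_states == s, n_perm, rng)
        state_results[s] = (delta, p, _verdict(p))
    pairwise = {}
    for i, a in enumerate(keep_states):
        for b in keep_states[i + 1:]:
            sub = np.isin(lab_states, (a, b))
            delta, p = _perm_test(rates[sub], lab_states[sub] == a, n_perm, rng)
            pairwise[(a, b)] = (delta, p, _verdict(p))
    return ShiftTest(state_results=state_results, pairwise=pairwise,
                     n_perm=n_perm, seed=seed, excluded_states=excluded)
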