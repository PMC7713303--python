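"""Seeded generators for trees, traits, habitat scenarios, and assemblages.

These generators produce data with the statistical structure the analysis
modules assume — ultrametric birth-death trees, traits evolved under
BM/OU/EB/WN, habitat labels with configurable additive shifts and
terminal-edge rate multipliers — so every downstream stage can be exercised
and power-tested without any external dataset.

Randomness is NumPy ``Generator`` based (PCG64).  Every public entry point
takes either a seed or a ``Generator``; a :class:`SimScenario` seed is split
with ``SeedSequence.spawn`` into independent streams for the tree, the trait,
and the habitat stage, so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from islandtraits.errors import FitError, InvalidTreeError
from islandtraits.phylo import Phylogeny, extract_clade, parse_newick

__all__ = [
    "SimScenario",
    "simulate_tree",
    "simulate_trait",
    "apply_habitat_scenario",
    "make_assemblages",
    "simulate_scenario",
]

HABITATS = ("mainland", "continental_island", "volcanic_island")


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimScenario:
    """Full description of one synthetic study condition.

    Defaults mirror a desk-scale analogue of a tropical plant radiation:
    150 extant species from a pure-birth tree (speciation 0.1 /Myr, so tree
    height on the order of 50 Myr), a log10-scale trait under constrained
    (OU) evolution, three habitat categories assigned i.i.d. with mainland
    most frequent, and a 10% widespread fraction.
    """

    n_tips: int = 150
    birth: float = 0.1          # speciation rate, /Myr
    death: float = 0.0          # extinction rate, /Myr
    trait_model: str = "OU"
    trait_params: dict = field(default_factory=lambda: {
        "sigma2": 0.02, "alpha": 0.05, "z0": 0.8,
    })
    habitat_scheme: str = "random"          # or "clade_block"
    habitat_probs: dict = field(default_factory=lambda: {
        "mainland": 0.5, "continental_island": 0.3, "volcanic_island": 0.2,
    })
    block_counts: dict = field(default_factory=dict)  # clade_block: habitat -> n clades
    trait_shift: dict = field(default_factory=dict)   # habitat -> additive shift (log10)
    rate_multiplier: dict = field(default_factory=dict)  # habitat -> terminal-edge SD factor
    widespread_fraction: float = 0.0
    seed: int = 0

    def as_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_tips: int, birth: float = 0.1, death: float = 0.0,
                  seed=None, max_retries: int = 10_000) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant tips.

    Forward event simulation from a root with two lineages; when the extant
    count first reaches ``n_tips`` the present is set a further
    ``Exp(n (birth+death))`` waiting time later (stopping just before the
    next event), extinct lineages are pruned, and tips are labeled
    ``t1..tN`` in tree order.  Runs that go extinct (or whose pruned tree
    drops below ``n_tips``) are retried up to ``max_retries`` times.
    """
    if n_tips < 2:
        raise InvalidTreeError("need n_tips >= 2")
    if not (birth > death >= 0):
        raise InvalidTreeError("need birth > death >= 0")
    rng = _rng(seed)
    for _ in range(max_retries):
        tree = _simulate_once(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise FitError(f"birth-death conditioning failed after {max_retries} attempts")


def _simulate_once(n_tips, birth, death, rng):
    # node records: (parent, birth_time); lineages: list of live node ids
    parent = [-1, 0, 0]
    btime = [0.0, 0.0, 0.0]
    alive = [1, 2]
    t = 0.0
    rate = birth + death
    while len(alive) < n_tips:
        if not alive:
            return None
        t += rng.exponential(1.0 / (len(alive) * rate))
        i = alive[rng.integers(len(alive))]
        if rng.random() < birth / rate:
            for _ in range(2):
                parent.append(i)
                btime.append(t)
                alive.append(len(parent) - 1)
            alive.remove(i)
        else:
            alive.remove(i)
    present = t + rng.exponential(1.0 / (len(alive) * rate))

    children = {}
    for v, p in enumerate(parent):
        children.setdefault(p, []).append(v)
    alive_set = set(alive)
    counter = [0]

    def build(v):
        """(newick fragment without stem, time the fragment's root splits)."""
        ch = children.get(v, [])
        if not ch:
            if v not in alive_set:
                return None
            counter[0] += 1
            return (f"t{counter[0]}", present)
        subs = [r for r in (build(c) for c in ch) if r is not None]
        if not subs:
            return None
        if len(subs) == 1:
            return subs[0]  # extinct sibling: splice through
        split = btime[ch[0]]  # children are born at this node's split event
        frag = "(" + ",".join(f"{s}:{float(tv - split)!r}" for s, tv in subs) + ")"
        return (frag, split)

    res = build(0)
    if res is None:
        return None
    frag, split = res
    if not frag.startswith("(") or split > 0.0:
        return None  # fewer than 2 survivors from the root split
    tree = parse_newick(frag + ";")
    if tree.n_tips != n_tips:
        return None
    return tree


# ---------------------------------------------------------------------------
# traits


def simulate_trait(tree: Phylogeny, model: str, params: dict, seed=None,
                   edge_sd_factor=None):
    """Simulate one trait on ``tree`` by root-to-tip recursion.

    Returns ``(tips, node_states)``: a dict label -> value and the full array
    of true states per node (postorder ids), for recovery tests.

    ``edge_sd_factor`` optionally maps node id -> factor multiplying the
    standard deviation of that edge's stochastic increment (used for
    habitat rate-multiplier scenarios; identity by default).
    """
    rng = _rng(seed)
    s2 = float(params["sigma2"])
    if s2 < 0:
        raise FitError("sigma2 must be >= 0")
    states = np.zeros(tree.n_nodes)
    depths = tree.depths()

    if model == "WN":
        mu = float(params["mu"])
        states[:] = mu
        for t in tree.tip_ids:
            f = 1.0 if edge_sd_factor is None else edge_sd_factor.get(int(t), 1.0)
            states[t] = mu + rng.normal(0.0, np.sqrt(s2)) * f
        tips = {lab: float(states[t]) for t, lab in zip(tree.tip_ids, tree.tip_labels)}
        return tips, states

    z0 = float(params["z0"])
    if model == "OU":
        alpha = float(params["alpha"])
        if alpha < 0:
            raise FitError("alpha must be >= 0")
        theta = float(params.get("theta", z0))
    elif model == "EB":
        a = float(params["a"])
        if a > 0:
            raise FitError("EB exponent a must be <= 0")
    elif model != "BM":
        raise FitError(f"unknown trait model {model!r}")

    states[tree.root] = z0
    for v in range(tree.n_nodes - 2, -1, -1):  # root-to-tip order
        p = tree.parent[v]
        ell = float(tree.length[v])
        x = states[p]
        if model == "BM":
            mean, var = x, s2 * ell
        elif model == "OU":
            if alpha == 0.0:
                mean, var = x, s2 * ell
            else:
                e = np.exp(-alpha * ell)
                mean = theta + (x - theta) * e
                var = s2 * (-np.expm1(-2.0 * alpha * ell)) / (2.0 * alpha)
        else:  # EB: rate decays with time from the root
            t1, t2 = depths[p], depths[v]
            if a == 0.0:
                var = s2 * ell
            else:
                var = s2 * (np.expm1(a * t2) - np.expm1(a * t1)) / a
            mean = x
        f = 1.0 if edge_sd_factor is None else edge_sd_factor.get(int(v), 1.0)
        states[v] = mean + rng.normal(0.0, np.sqrt(max(var, 0.0))) * f
    tips = {lab: float(states[t]) for t, lab in zip(tree.tip_ids, tree.tip_labels)}
    return tips, states


# ---------------------------------------------------------------------------
# habitat scenarios


def _assign_random(tree, probs, rng):
    habs = list(probs)
    p = np.array([probs[h] for h in habs], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise FitError(f"habitat probabilities must sum to 1, got {p.sum()}")
    draw = rng.choice(len(habs), size=tree.n_tips, p=p)
    return {lab: habs[d] for lab, d in zip(tree.tip_labels, draw)}


def _assign_clade_block(tree, block_counts, rng):
    """Assign whole clades to habitats, producing phylogenetic clustering."""
    tsets = tree.tip_sets()
    # candidate clades: internal nodes with 3..n/2 tips, non-nested greedy pick
    internal = [v for v in range(tree.n_nodes)
                if tree.children[v] and 3 <= len(tsets[v]) <= tree.n_tips // 2]
    order = rng.permutation(len(internal))
    need = sum(block_counts.values())
    chosen, covered = [], set()
    for j in order:
        v = internal[j]
        tips = set(tsets[v].tolist())
        if tips & covered:
            continue
        chosen.append(v)
        covered |= tips
        if len(chosen) == need:
            break
    if len(chosen) < need:
        raise FitError(
            f"clade_block scheme needs {need} disjoint clades, found {len(chosen)}"
        )
    assignment = {}
    it = iter(chosen)
    for hab, cnt in block_counts.items():
        for _ in range(cnt):
            v = next(it)
            for t in tsets[v]:
                assignment[tree.tip_labels[t]] = hab
    # remaining tips: spread over the habitats uniformly
    habs = list(block_counts)
    for lab in tree.tip_labels:
        if lab not in assignment:
            assignment[lab] = habs[rng.integers(len(habs))]
    return assignment


def apply_habitat_scenario(tree: Phylogeny, scenario: SimScenario, seed=None):
    """Assign habitats and simulate the trait with the scenario's shifts and
    terminal-edge rate multipliers applied.

    Returns ``(habitat, tips, node_states)`` where ``habitat`` maps tip label
    to habitat (possibly ``"widespread"``), ``tips`` maps label to final trait
    value, and ``node_states`` are the true (pre-shift) node states.
    """
    base = np.random.SeedSequence(scenario.seed if seed is None else seed)
    s_tree, s_hab, s_trait, s_wide = base.spawn(4)
    rng_h = np.random.default_rng(s_hab)

    if scenario.habitat_scheme == "random":
        habitat = _assign_random(tree, scenario.habitat_probs, rng_h)
    elif scenario.habitat_scheme == "clade_block":
        habitat = _assign_clade_block(tree, scenario.block_counts or
                                      {h: 1 for h in HABITATS}, rng_h)
    else:
        raise FitError(f"unknown habitat scheme {scenario.habitat_scheme!r}")

    factors = {}
    if scenario.rate_multiplier:
        for t, lab in zip(tree.tip_ids, tree.tip_labels):
            m = scenario.rate_multiplier.get(habitat[lab], 1.0)
            if m <= 0:
                raise FitError("rate multipliers must be > 0")
            if m != 1.0:
                factors[int(t)] = m

    tips, node_states = simulate_trait(
        tree, scenario.trait_model, scenario.trait_params,
        seed=np.random.default_rng(s_trait),
        edge_sd_factor=factors or None,
    )
    if scenario.trait_shift:
        for lab in tips:
            tips[lab] += scenario.trait_shift.get(habitat[lab], 0.0)

    if scenario.widespread_fraction > 0:
        rng_w = np.random.default_rng(s_wide)
        k = int(round(scenario.widespread_fraction * tree.n_tips))
        for i in rng_w.choice(tree.n_tips, size=k, replace=False):
            habitat[tree.tip_labels[i]] = "widespread"
    return habitat, tips, node_states


def simulate_scenario(scenario: SimScenario):
    """Full realization: tree + habitat + trait + truth metadata."""
    base = np.random.SeedSequence(scenario.seed)
    s_tree, *_ = base.spawn(4)
    tree = simulate_tree(scenario.n_tips, scenario.birth, scenario.death,
                         seed=np.random.default_rng(s_tree))
    habitat, tips, node_states = apply_habitat_scenario(tree, scenario)
    truth = {"scenario": scenario.as_dict(), "tree_height": tree.height}
    return tree, habitat, tips, node_states, truth


# ---------------------------------------------------------------------------
# assemblages


def make_assemblages(tree: Phylogeny, overlap: float, sizes=(30, 30), seed=None):
    """Two tip sets with a controlled shared fraction.

    ``overlap`` in [0, 1]: 1 gives identical sets (sizes permitting), 0 gives
    disjoint sets; intermediate values share ``round(overlap * min(sizes))``
    tips.
    """
    if not 0.0 <= overlap <= 1.0:
        raise FitError("overlap must lie in [0, 1]")
    n1, n2 = sizes
    n_shared = int(round(overlap * min(n1, n2)))
    total = n1 + n2 - n_shared
    if total > tree.n_tips:
        raise FitError(f"sizes {sizes} with overlap {overlap} need {total} tips, "
                       f"tree has {tree.n_tips}")
    rng = _rng(seed)
    picks = rng.choice(tree.n_tips, size=total, replace=False)
    labels = [tree.tip_labels[i] for i in picks]
    shared = labels[:n_shared]
    u1 = labels[n_shared:n_shared + (n1 - n_shared)]
    u2 = labels[n_shared + (n1 - n_shared):]
    return set(shared) | set(u1), set(shared) | set(u2)
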