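"""PhyloSor phylogenetic beta-diversity, partitioned into turnover and
nestedness.

For two assemblages (tip sets) on one tree, an edge is *present* in an
assemblage iff at least one of its tips descends from that edge.  With

* ``a`` — total length of edges present in both assemblages,
* ``b`` / ``c`` — length unique to assemblage 1 / 2,

the Sorensen-family dissimilarities are::

    beta_sor = (b + c) / (2 a + b + c)            # total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))        # turnover (lineage replacement)
    beta_sne = beta_sor - beta_sim                # nestedness (length difference)

All three lie in [0, 1]; identical assemblages give zeros, and on a star
tree with unit branches ``beta_sor`` reduces to the classical species-level
Sorensen dissimilarity.  By default edge presence is evaluated on the full
supplied tree, root path included; ``mrca_only=True`` restricts each pair to
the subtree below the MRCA of their union.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from islandtraits.errors import DataError
from islandtraits.phylo import Phylogeny, extract_clade, normalize_label

__all__ = [
    "EdgeComponents",
    "BetaPartition",
    "edge_components",
    "phylosor_pair",
    "phylosor_partition",
]


@dataclass(frozen=True)
class EdgeComponents:
    """Shared (a) and unique (b, c) branch lengths of two assemblages, Myr."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class BetaPartition:
    """PhyloSor dissimilarity and its additive components."""

    beta_sor: float
    beta_sim: float
    beta_sne: float

    @property
    def dominant(self) -> str:
        return "turnover" if self.beta_sim >= self.beta_sne else "nestedness"


def _tip_mask(tree: Phylogeny, tips) -> np.ndarray:
    idx = tree.label_index()
    mask = np.zeros(tree.n_tips, dtype=bool)
    unknown = []
    for t in tips:
        k = idx.get(normalize_label(str(t)))
        if k is None:
            unknown.append(t)
        else:
            mask[k] = True
    if unknown:
        raise DataError(f"tips not in tree: {sorted(map(str, unknown))}")
    if not mask.any():
        raise DataError("assemblage is empty")
    return mask


def edge_components(tree: Phylogeny, set1, set2, mrca_only: bool = False) -> EdgeComponents:
    """Shared and unique branch lengths of two tip sets.

    With ``mrca_only`` the tree is first pruned to the union of the two sets
    (rooted at their MRCA); otherwise the full tree's root path counts.
    """
    m1 = _tip_mask(tree, set1)
    m2 = _tip_mask(tree, set2)
    if mrca_only:
        union = [l for l, k in zip(tree.tip_labels, m1 | m2) if k]
        if len(union) >= 2:
            tree = extract_clade(tree, union)
            m1 = _tip_mask(tree, [l for l in set1])
            m2 = _tip_mask(tree, [l for l in set2])
    # edge e (child node v) is present in a set iff >= 1 tip of the set
    # descends from v
    in1 = np.zeros(tree.n_nodes, dtype=bool)
    in2 = np.zeros(tree.n_nodes, dtype=bool)
    pos_of = {int(t): i for i, t in enumerate(tree.tip_ids)}
    for v in range(tree.n_nodes):
        ch = tree.children[v]
        if not ch:
            in1[v] = m1[pos_of[v]]
            in2[v] = m2[pos_of[v]]
        else:
            in1[v] = any(in1[c] for c in ch)
            in2[v] = any(in2[c] for c in ch)
    e1, e2 = in1[: tree.n_nodes - 1], in2[: tree.n_nodes - 1]  # root excluded
    ln = tree.length[: tree.n_nodes - 1]
    a = float(ln[e1 & e2].sum())
    b = float(ln[e1 & ~e2].sum())
    c = float(ln[~e1 & e2].sum())
    return EdgeComponents(a=a, b=b, c=c)


def phylosor_pair(tree: Phylogeny, set1, set2, mrca_only: bool = False) -> BetaPartition:
    """PhyloSor partition for one assemblage pair."""
    ec = edge_components(tree, set1, set2, mrca_only=mrca_only)
    a, b, c = ec.a, ec.b, ec.c
    if a == b == c == 0.0:
        return BetaPartition(0.0, 0.0, 0.0)
    beta_sor = (b + c) / (2.0 * a + b + c)
    bmin = min(b, c)
    beta_sim = bmin / (a + bmin) if (a + bmin) > 0 else (1.0 if bmin > 0 else 0.0)
    return BetaPartition(beta_sor=beta_sor, beta_sim=beta_sim,
                         beta_sne=beta_sor - beta_sim)


def phylosor_partition(tree: Phylogeny, assemblages: dict,
                       mrca_only: bool = False) -> dict:
    """All pairwise PhyloSor partitions of named assemblages.

    ``assemblages`` maps name (e.g. habitat) -> tip set; returns
    ``{(name_a, name_b): BetaPartition}`` for every unordered pair, names in
    input order.
    """
    names = list(assemblages)
    if len(names) < 2:
        raise DataError("need >= 2 assemblages")
    return {
        (p, q): phylosor_pair(tree, assemblages[p], assemblages[q],
                              mrca_only=mrca_only)
        for p, q in combinations(names, 2)
    }
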