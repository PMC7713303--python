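"""Rooted time-calibrated trees: Newick I/O, tree algebra, clade extraction.

The :class:`Phylogeny` container stores a rooted tree with branch lengths in
Myr as flat arrays indexed in deterministic postorder (children kept in input
order, so tips appear left-to-right as written in the Newick string and the
root is always the last node).  Every downstream stage — GLS covariances,
likelihood pruning, ridge-regression path matrices, beta-diversity edge sets —
consumes either the arrays directly or the :class:`TreeMatrices` bundle.

Newick parsing and writing delegate to :mod:`dendropy`; labels keep their
underscores verbatim (``preserve_underscores``), and :func:`normalize_label`
implements the matching convention used against trait tables (trim, collapse
whitespace, underscore treated as space, case preserved).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

from islandtraits.errors import (
    InvalidTreeError,
    MissingBranchLengthError,
    NewickParseError,
)

__all__ = [
    "Phylogeny",
    "TreeMatrices",
    "normalize_label",
    "parse_newick",
    "read_newick",
    "write_newick",
    "validate_ultrametric",
    "tree_matrices",
    "extract_clade",
]

#: default relative tolerance for declaring a tree ultrametric; time-calibrated
#: trees routinely carry rounding noise of this order in their branch lengths
DEFAULT_ULTRAMETRIC_RTOL = 1e-3

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Normalize a taxon label for comparison: trim, collapse whitespace,
    treat underscores as spaces.  Case is preserved (binomials are
    case-sensitive in practice)."""
    return _WS.sub(" ", label.replace("_", " ").strip())


@dataclass(frozen=True)
class Phylogeny:
    """Rooted tree with branch lengths, nodes indexed in postorder.

    Attributes
    ----------
    parent : (n_nodes,) int array; ``parent[root] == -1``.
    length : (n_nodes,) float array of parent-edge lengths in Myr; the root
        entry is 0 (the root has no parent edge).
    children : tuple of tuples of child ids, input order.
    tip_ids : node ids of the tips, in left-to-right Newick order.
    tip_labels : labels aligned with ``tip_ids``; unique after normalization.
    """

    parent: np.ndarray
    length: np.ndarray
    children: tuple
    tip_ids: np.ndarray
    tip_labels: tuple

    def __post_init__(self):
        if np.any(self.length < 0):
            bad = np.nonzero(self.length < 0)[0]
            raise InvalidTreeError(f"negative branch length on edges {bad.tolist()}")
        norm = [normalize_label(l) for l in self.tip_labels]
        if len(set(norm)) != len(norm):
            dups = sorted({l for l in norm if norm.count(l) > 1})
            raise InvalidTreeError(f"duplicate tip labels: {dups}")

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def depths(self) -> np.ndarray:
        """Time from the root to every node (root-first accumulation)."""
        d = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):  # reverse postorder, skip root
            d[v] = d[self.parent[v]] + self.length[v]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[self.tip_ids]

    @property
    def height(self) -> float:
        return float(self.tip_depths().max())

    def label_index(self) -> dict:
        """normalized label -> position in tip order."""
        return {normalize_label(l): i for i, l in enumerate(self.tip_labels)}

    def is_ultrametric(self, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL) -> bool:
        ok, _ = validate_ultrametric(self, rel_tol)
        return ok

    # -- structure helpers ------------------------------------------------

    def tip_sets(self) -> list:
        """Per-node sorted arrays of descendant tip *positions* (tip order)."""
        pos_of = {int(t): i for i, t in enumerate(self.tip_ids)}
        sets: list = [None] * self.n_nodes
        for v in range(self.n_nodes):
            ch = self.children[v]
            if not ch:
                sets[v] = np.array([pos_of[v]], dtype=int)
            else:
                sets[v] = np.concatenate([sets[c] for c in ch])
        return sets

    def __repr__(self):
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g})"


# -- construction ---------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    children: list = [() for _ in range(n)]
    tip_ids, tip_labels = [], []
    for i, nd in enumerate(nodes):
        kids = nd.child_nodes()
        children[i] = tuple(index[id(c)] for c in kids)
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise MissingBranchLengthError(
                    "edge without branch length (no default is assumed); "
                    f"node taxon={getattr(nd.taxon, 'label', None)!r}"
                )
            length[i] = float(nd.edge.length)
        if not kids:
            lab = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            if not lab:
                raise NewickParseError("unlabeled tip in Newick input")
            tip_ids.append(i)
            tip_labels.append(lab)
    return Phylogeny(
        parent=parent,
        length=length,
        children=tuple(children),
        tip_ids=np.array(tip_ids, dtype=int),
        tip_labels=tuple(tip_labels),
    )


def parse_newick(text: str):
    """Parse Newick ``text`` into a :class:`Phylogeny`.

    ``text`` may hold several trees (one per line or concatenated after the
    terminating semicolons); a single tree is returned bare, several are
    returned as a list in file order.

    Raises
    ------
    NewickParseError
        on malformed input, with dendropy's position diagnostics attached.
    MissingBranchLengthError
        when any non-root edge has no branch length.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several tokenizer error types
        if "Duplicate taxon labels" in str(exc):
            raise InvalidTreeError(f"duplicate tip labels: {exc}") from None
        raise NewickParseError(f"malformed Newick: {exc}") from None
    if len(tlist) == 0:
        raise NewickParseError("no trees found in Newick input")
    trees = [_from_dendropy(t) for t in tlist]
    return trees[0] if len(trees) == 1 else trees


def read_newick(path):
    """Read a single- or multi-tree Newick file (one tree per ``;``)."""
    with open(path) as fh:
        return parse_newick(fh.read())


def _subtree_newick(tree: Phylogeny, v: int, pos_label: dict) -> str:
    ch = tree.children[v]
    if not ch:
        lab = pos_label[v].replace(" ", "_")
        s = lab
    else:
        s = "(" + ",".join(_subtree_newick(tree, c, pos_label) for c in ch) + ")"
    if tree.parent[v] >= 0:
        s += f":{float(tree.length[v])!r}"
    return s


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick.  Branch lengths are written with ``repr`` (exact
    shortest round-trip form), so parse(write(t)) reproduces lengths bit-for-bit;
    spaces in labels are written as underscores."""
    pos_label = {int(t): lab for t, lab in zip(tree.tip_ids, tree.tip_labels)}
    return _subtree_newick(tree, tree.root, pos_label) + ";"


def validate_ultrametric(tree: Phylogeny, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL):
    """Return ``(ok, max_relative_deviation)`` of root-to-tip depths.

    A tree is ultrametric at ``rel_tol`` iff max |depth(tip) - T| / T <= rel_tol,
    with T the maximum tip depth.
    """
    d = tree.tip_depths()
    T = float(d.max())
    if T <= 0:
        return True, 0.0
    dev = float(np.abs(d - T).max() / T)
    return dev <= rel_tol, dev


# -- matrices -------------------------------------------------------------


@dataclass(frozen=True)
class TreeMatrices:
    """Patristic-distance, shared-time, and root-path matrices of a tree.

    ``D[i, j]`` is the patristic distance between tips i and j; ``S[i, j]``
    the root-to-MRCA depth (phylogenetic covariance base, with
    ``S[i, i]`` = depth of tip i); ``L[i, e]`` the length of edge e if e lies
    on the root-to-tip-i path, else 0.  Edge e is the postorder node id of
    the edge's child node (the root, which has no parent edge, is excluded),
    so edge order is stable across runs on the same parsed tree.
    """

    D: np.ndarray
    S: np.ndarray
    L: np.ndarray
    edge_ids: np.ndarray  # node ids (postorder) of the edges = columns of L
    tip_labels: tuple

    @property
    def tip_depths(self) -> np.ndarray:
        return np.diag(self.S).copy()


def tree_matrices(tree: Phylogeny) -> TreeMatrices:
    """Compute the :class:`TreeMatrices` bundle in one pass."""
    n = tree.n_tips
    depths = tree.depths()
    tsets = tree.tip_sets()

    S = np.zeros((n, n))
    for v in range(tree.n_nodes):
        ch = tree.children[v]
        for a in range(len(ch)):
            for b in range(a + 1, len(ch)):
                ta, tb = tsets[ch[a]], tsets[ch[b]]
                S[np.ix_(ta, tb)] = depths[v]
                S[np.ix_(tb, ta)] = depths[v]
    td = depths[tree.tip_ids]
    np.fill_diagonal(S, td)

    D = td[:, None] + td[None, :] - 2.0 * S
    np.fill_diagonal(D, 0.0)

    edge_ids = np.arange(tree.n_nodes - 1)  # all nodes but the root
    L = np.zeros((n, edge_ids.size))
    for i, t in enumerate(tree.tip_ids):
        v = int(t)
        while tree.parent[v] >= 0:
            L[i, v] = tree.length[v]
            v = tree.parent[v]
    return TreeMatrices(D=D, S=S, L=L, edge_ids=edge_ids, tip_labels=tree.tip_labels)


# -- clade extraction -----------------------------------------------------


def _resolve_taxa(tree: Phylogeny, taxa) -> np.ndarray:
    idx = tree.label_index()
    keep, missing = [], []
    for t in taxa:
        k = idx.get(normalize_label(t))
        (missing if k is None else keep).append(t if k is None else k)
    if missing:
        raise InvalidTreeError(f"taxa not found in tree: {sorted(missing)}")
    return np.array(sorted(keep), dtype=int)


def extract_clade(tree: Phylogeny, taxa) -> Phylogeny:
    """Induced subtree on ``taxa`` (>= 2 labels), rooted at their MRCA.

    Unsampled lineages are pruned and pass-through (degree-2) nodes are
    collapsed by summing branch lengths, so pairwise patristic distances among
    the retained tips are preserved exactly.
    """
    keep_pos = _resolve_taxa(tree, taxa)
    if keep_pos.size < 2:
        raise InvalidTreeError("extract_clade needs at least 2 taxa")
    keep_tip_ids = set(int(tree.tip_ids[p]) for p in keep_pos)

    n_keep = np.zeros(tree.n_nodes, dtype=int)
    for v in range(tree.n_nodes):
        if not tree.children[v]:
            n_keep[v] = 1 if v in keep_tip_ids else 0
        else:
            n_keep[v] = sum(n_keep[c] for c in tree.children[v])
    total = n_keep[tree.root]
    # MRCA: deepest node whose subtree still contains all kept tips
    mrca = tree.root
    while True:
        carriers = [c for c in tree.children[mrca] if n_keep[c] == total]
        if carriers:
            mrca = carriers[0]
        else:
            break

    pos_label = {int(t): lab for t, lab in zip(tree.tip_ids, tree.tip_labels)}

    def build(v: int, stem: float) -> str:
        # returns newick fragment for the pruned subtree below v, with
        # accumulated pass-through length `stem` on its edge
        if not tree.children[v]:
            frag = pos_label[v].replace(" ", "_")
        else:
            kept_ch = [c for c in tree.children[v] if n_keep[c] > 0]
            if len(kept_ch) == 1:
                return build(kept_ch[0], stem + tree.length[kept_ch[0]])
            frag = "(" + ",".join(build(c, tree.length[c]) for c in kept_ch) + ")"
        return frag + f":{float(stem)!r}"

    kept_ch = [c for c in tree.children[mrca] if n_keep[c] > 0]
    newick = "(" + ",".join(build(c, tree.length[c]) for c in kept_ch) + ");"
    sub = parse_newick(newick)
    assert isinstance(sub, Phylogeny)
    return sub
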