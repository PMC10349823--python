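"""Ultrametric trees and the phylogenetic covariance matrix Ω.

The hierarchical models in this package pool family-level intercepts and
temperature slopes through Ω, the matrix of shared root-to-ancestor path
lengths among tips of an ultrametric tree: entry (i, j) is the depth of the
most recent common ancestor of tips i and j, and the diagonal is the tree
height.  Ω is symmetric positive semi-definite by construction and is the
Brownian-motion trait covariance up to a rate constant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "PhyloTree",
    "PhyloCovariance",
    "read_newick",
    "phylo_vcv",
    "scale_unit_height",
    "pagel_lambda_transform",
    "simulate_pure_birth",
]

#: relative tolerance on root-to-tip depth spread for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


@dataclass
class PhyloTree:
    """An ultrametric phylogeny with branch lengths in arbitrary time units."""

    tree: dendropy.Tree

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def tip_depths(self) -> dict[str, float]:
        dists = self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        return {leaf.taxon.label: leaf.root_distance for leaf in self.tree.leaf_node_iter()}

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        h = depths.max()
        if h <= 0:
            return False
        return (depths.max() - depths.min()) <= rtol * h

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class PhyloCovariance:
    """Ω: shared-path-length covariance among an ordered list of taxa."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("phylogenetic covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(self.matrix).min()
        if eigmin < -1e-8 * max(1.0, np.abs(self.matrix).max()):
            raise ValueError("phylogenetic covariance must be positive semi-definite")

    @property
    def height(self) -> float:
        return float(self.matrix.diagonal().max())

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"labels not in covariance: {sorted(missing)}")
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(list(labels), self.matrix[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def read_newick(text: str, check_ultrametric: bool = True) -> PhyloTree:
    """Parse a Newick string with branch lengths into a :class:`PhyloTree`.

    Raises :class:`NewickError` naming the offending position on a parse
    failure, on missing branch lengths, and (when ``check_ultrametric``) on
    unequal root-to-tip depths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise NewickError("a phylogeny needs at least 2 tips")
    labels = []
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError("every tip must be labelled")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        raise NewickError("tip labels must be unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise NewickError(
                f"missing branch length above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
        if edge.length < 0:
            raise NewickError("negative branch length")
    out = PhyloTree(tree)
    if check_ultrametric and not out.is_ultrametric():
        depths = out.tip_depths()
        raise NewickError(
            f"tree is not ultrametric: tip depths range "
            f"{min(depths.values()):.6g} to {max(depths.values()):.6g}"
        )
    return out


def phylo_vcv(tree: PhyloTree) -> PhyloCovariance:
    """Ω from shared path lengths: (i, j) ↦ depth of MRCA(i, j); (i, i) ↦ height.

    Computed as ``(depth_i + depth_j − patristic(i, j)) / 2``, which equals the
    MRCA depth on any tree (polytomies included).
    """
    if not tree.is_ultrametric():
        raise ValueError("phylo_vcv requires an ultrametric tree")
    labels = tree.tips
    n = len(labels)
    depths = tree.tip_depths()
    d = np.array([depths[l] for l in labels])
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    mat = np.zeros((n, n))
    for i, li in enumerate(labels):
        mat[i, i] = d[i]
        for j in range(i + 1, n):
            patristic = pdm.patristic_distance(taxa[li], taxa[labels[j]])
            mat[i, j] = mat[j, i] = 0.5 * (d[i] + d[j] - patristic)
    # exact ultrametric diagonal: force shared height
    np.fill_diagonal(mat, d.max())
    mat[mat < 0] = 0.0
    return PhyloCovariance(labels, mat)


def scale_unit_height(vcv: PhyloCovariance) -> PhyloCovariance:
    """Divide every entry by the tree height so the diagonal is exactly 1."""
    h = vcv.height
    if h <= 0:
        raise ValueError("tree height must be positive")
    return PhyloCovariance(list(vcv.labels), vcv.matrix / h)


def pagel_lambda_transform(vcv: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's λ: multiply off-diagonal covariances by λ ∈ [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    mat = vcv.matrix * lam
    np.fill_diagonal(mat, vcv.matrix.diagonal())
    return PhyloCovariance(list(vcv.labels), mat)


def simulate_pure_birth(
    n_tips: int, seed: int, birth_rate: float = 1.0, prefix: str = "t"
) -> PhyloTree:
    """Simulate an ultrametric Yule (pure-birth) tree with ``n_tips`` tips.

    Lineages split at rate ``birth_rate`` each; waiting times are exponential
    in the number of extant lineages, and all surviving lineages are extended
    to the present, so the result is exactly ultrametric.  Deterministic for a
    fixed seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    class _Node:
        __slots__ = ("children", "length", "label")

        def __init__(self):
            self.children: list[_Node] = []
            self.length = 0.0
            self.label: str | None = None

    root = _Node()
    a, b = _Node(), _Node()
    root.children = [a, b]
    active = [a, b]
    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for lin in active:
            lin.length += wait
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        left, right = _Node(), _Node()
        parent.children = [left, right]
        active.extend([left, right])
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for lin in active:
        lin.length += wait
    for i, lin in enumerate(active):
        lin.label = f"{prefix}{i + 1}"

    def _newick(node: _Node) -> str:
        if not node.children:
            return f"{node.label}:{node.length!r}"
        inner = ",".join(_newick(c) for c in node.children)
        return f"({inner}):{node.length!r}" if node is not root else f"({inner})"

    return read_newick(_newick(root) + ";")
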