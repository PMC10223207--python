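"""Phylogenetic plumbing: Newick parsing, the tip-sharing variance-
covariance matrix, and Felsenstein's independent contrasts.

Trees are held by dendropy; this module wraps parsing/validation and
derives the two structures the signal test needs: the Brownian-motion
covariance matrix V (V[i,j] = root-to-MRCA path length shared by tips i
and j) and the standardized independent contrasts, whose variance serves
as the tip-shuffle permutation statistic.  Because contrast values are a
fixed linear map of the tip values, the map is also exposed as a matrix
(:func:`contrast_operator`) so thousands of permutations cost one matrix
product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateContrastError,
    NewickParseError,
    ValidationError,
)

__all__ = [
    "PhyloTree",
    "VCVMatrix",
    "ContrastSet",
    "parse_newick",
    "read_newick",
    "vcv_matrix",
    "independent_contrasts",
    "contrast_operator",
]

log = logging.getLogger(__name__)


class PhyloTree:
    """A rooted tree with unique tip labels and nonnegative branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise ValidationError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(
                    f"negative branch length on edge above "
                    f"{_node_name(edge.head_node)}"
                )
        self.tip_labels: tuple[str, ...] = tuple(labels)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "duplicate" in str(exc).lower():
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- structure ---------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        depths = _node_depths(self._tree)
        return max(depths[leaf] for leaf in self._tree.leaf_node_iter())

    def require_branch_lengths(self) -> None:
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError(
                    f"missing branch length on edge above "
                    f"{_node_name(edge.head_node)}"
                )

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_tips} tips)"


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick tree (quoted labels and underscores OK)."""
    return PhyloTree.from_newick(text)


def read_newick(path) -> PhyloTree:
    return PhyloTree.read(path)


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return repr(node.taxon.label)
    tips = [l.taxon.label for l in node.leaf_iter()]
    return f"MRCA of {tips[:3]}"


def _node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


# ---------------------------------------------------------------------------
# Variance-covariance matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VCVMatrix:
    """Tip-sharing covariance matrix of a tree under Brownian motion."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def align(self, traits: Mapping[str, float]) -> np.ndarray:
        """Trait values ordered to match ``labels``."""
        missing = [l for l in self.labels if l not in traits]
        if missing:
            raise ValidationError(f"traits missing for tips: {missing}")
        return np.array([float(traits[l]) for l in self.labels])


def vcv_matrix(tree: PhyloTree) -> VCVMatrix:
    """V[i,j] = root-to-MRCA(i,j) path length; V[i,i] = depth of tip i."""
    tree.require_branch_lengths()
    dt = tree.dendropy_tree
    depths = _node_depths(dt)
    leaves = list(dt.leaf_node_iter())
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    v = np.zeros((n, n))
    for leaf in leaves:
        v[index[leaf], index[leaf]] = depths[leaf]
    # the MRCA of any cross-child pair of tips at an internal node is that node
    for node in dt.preorder_internal_node_iter():
        children = node.child_nodes()
        tip_groups = [[index[l] for l in c.leaf_iter()] for c in children]
        for a in range(len(tip_groups)):
            for b in range(a + 1, len(tip_groups)):
                for i in tip_groups[a]:
                    for j in tip_groups[b]:
                        v[i, j] = v[j, i] = depths[node]
    labels = tuple(l.taxon.label for l in leaves)
    return VCVMatrix(labels=labels, matrix=v)


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSet:
    """Independent contrasts: raw node differences with their expected
    variances, plus the standardized values ``contrast / sqrt(variance)``."""

    contrasts: tuple[tuple[float, float], ...]

    @property
    def standardized(self) -> np.ndarray:
        return np.array([c / np.sqrt(v) for c, v in self.contrasts])

    @property
    def variance_of_standardized(self) -> float:
        return float(np.var(self.standardized, ddof=1))


def _resolved_copy(tree: PhyloTree) -> dendropy.Tree:
    """Clone and resolve polytomies deterministically (left-to-right) into
    zero-length bifurcations."""
    dt = tree.dendropy_tree.clone(depth=1)
    for node in list(dt.preorder_internal_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            first, second = children[0], children[1]
            node.remove_child(first)
            node.remove_child(second)
            merged = dendropy.Node()
            merged.edge.length = 0.0
            merged.add_child(first)
            merged.add_child(second)
            node.insert_child(0, merged)
    return dt


def _contrast_rows(
    tree: PhyloTree, epsilon: float | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Pruning pass returning the linear map from tip values to raw
    contrasts, the contrast variances, and the tip order.

    Node values are variance-weighted averages of daughters and the parent
    edge is lengthened by v1*v2/(v1+v2), so each returned row applied to the
    tip vector yields one raw contrast.
    """
    tree.require_branch_lengths()
    dt = _resolved_copy(tree)
    leaves = list(dt.leaf_node_iter())
    labels = tuple(l.taxon.label for l in leaves)
    index = {l.taxon.label: i for i, l in enumerate(leaves)}
    n = len(leaves)
    if epsilon is None:
        epsilon = 1e-8 * max(tree.depth(), 1.0)

    rows: list[np.ndarray] = []
    variances: list[float] = []

    def prune(node) -> tuple[np.ndarray, float]:
        """Return (coefficient vector of the node value, adjusted edge length)."""
        if node.is_leaf():
            coeff = np.zeros(n)
            coeff[index[node.taxon.label]] = 1.0
            return coeff, (node.edge.length or 0.0)
        (c1, v1), (c2, v2) = (prune(ch) for ch in node.child_nodes())
        cv = v1 + v2
        if cv == 0.0:
            log.warning(
                "zero contrast variance at %s; adding epsilon %.3g",
                _node_name(node),
                epsilon,
            )
            cv = epsilon
            if cv == 0.0:
                raise DegenerateContrastError(
                    f"zero combined daughter branch length at {_node_name(node)}"
                )
        rows.append(c1 - c2)
        variances.append(cv)
        if v1 == 0.0 and v2 == 0.0:
            value = 0.5 * (c1 + c2)
            extra = 0.0
        elif v1 == 0.0:
            value, extra = c1, 0.0
        elif v2 == 0.0:
            value, extra = c2, 0.0
        else:
            w1, w2 = 1.0 / v1, 1.0 / v2
            value = (w1 * c1 + w2 * c2) / (w1 + w2)
            extra = v1 * v2 / (v1 + v2)
        edge = (node.edge.length or 0.0) if node.parent_node is not None else 0.0
        return value, edge + extra

    prune(dt.seed_node)
    return np.array(rows), np.array(variances), labels


def contrast_operator(
    tree: PhyloTree, epsilon: float | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Matrix L with L @ x = standardized contrasts of tip values x
    (x ordered as the returned tip labels)."""
    rows, variances, labels = _contrast_rows(tree, epsilon)
    return rows / np.sqrt(variances)[:, None], labels


def independent_contrasts(
    tree: PhyloTree,
    traits: Mapping[str, float],
    epsilon: float | None = None,
) -> ContrastSet:
    """Felsenstein's independent contrasts of one trait on a tree.

    Polytomies are resolved left-to-right into zero-length bifurcations, so
    a tree with n tips always yields n-1 contrasts.
    """
    rows, variances, labels = _contrast_rows(tree, epsilon)
    missing = [l for l in labels if l not in traits]
    if missing:
        raise ValidationError(f"traits missing for tips: {missing}")
    x = np.array([float(traits[l]) for l in labels])
    raw = rows @ x
    return ContrastSet(contrasts=tuple(zip(raw.tolist(), variances.tolist())))
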