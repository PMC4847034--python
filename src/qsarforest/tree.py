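"""Binary classification trees with Gini splitting and bounded pruning.

Trees are grown CART-style: at each node every candidate descriptor is
scanned, with candidate thresholds placed at the midpoints between
consecutive distinct sorted values, and the split maximizing the weighted
decrease in Gini impurity is taken.  A node is not split when it is pure,
holds fewer samples than ``min_split_size``, or no split reduces impurity.
Rows whose value equals the threshold route LEFT (the "meets criterion"
side, v <= t).

After growing, the tree is pruned bottom-up: any split whose subtree lies
within the bottom ``max_prune_levels`` levels of the grown tree may be
collapsed into a leaf, and the pruned tree minimizing the number of
misclassified training compounds is returned (ties go to the smaller
tree).  The collapse decisions in disjoint subtrees are independent, so a
post-order dynamic program finds the exact optimum.

Tie-breaking among equal-decrease splits is fixed — lowest descriptor
column index, then smallest threshold — so fitting is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .dataset import Dataset, DescriptorMatrix

__all__ = [
    "Leaf",
    "Split",
    "TreeNode",
    "DecisionTree",
    "TreeFitConfig",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "prune_tree",
    "fit_tree",
    "tree_predict",
]

# strictly positive impurity decrease required to accept a split; guards
# against float round-off manufacturing spurious splits on pure-ish nodes
_MIN_DECREASE = 1e-12


@dataclass(frozen=True)
class Leaf:
    n_binders: int
    n_nonbinders: int

    @property
    def n_total(self) -> int:
        return self.n_binders + self.n_nonbinders

    @property
    def p_binder(self) -> float:
        return self.n_binders / self.n_total

    @property
    def class_label(self) -> int:
        return 1 if self.p_binder >= 0.5 else 0

    @property
    def misclassified(self) -> int:
        return min(self.n_binders, self.n_nonbinders)


@dataclass(frozen=True)
class Split:
    descriptor_name: str
    threshold: float
    left: "TreeNode"   # rows with value <= threshold ("meets criterion")
    right: "TreeNode"


TreeNode = Union[Leaf, Split]


@dataclass(frozen=True)
class TreeFitConfig:
    """Tree parameters; the defaults are the model's canonical settings
    (minimum node size to split 10, at most 3 levels pruned, Gini index)."""

    min_split_size: int = 10
    max_prune_levels: int = 3
    split_criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.min_split_size < 1:
            raise ValueError("min_split_size must be positive")
        if self.max_prune_levels < 0:
            raise ValueError("max_prune_levels must be non-negative")
        if self.split_criterion != "gini":
            raise ValueError("only the Gini diversity index is supported")


@dataclass
class DecisionTree:
    root: TreeNode
    used_descriptors: frozenset = field(default_factory=frozenset)
    training_misclassified: int = 0

    def predict_row(self, row: Mapping[str, float]) -> float:
        return tree_predict(self, row)

    def predict_matrix(self, matrix: DescriptorMatrix) -> np.ndarray:
        """Vectorized p_binder for every chemical of a descriptor matrix."""
        missing = self.used_descriptors - set(matrix.descriptor_names)
        if missing:
            raise KeyError(f"matrix lacks descriptors: {sorted(missing)}")
        out = np.empty(matrix.n_chemicals, dtype=float)
        idx = np.arange(matrix.n_chemicals)
        self._route(self.root, matrix, idx, out)
        return out

    def _route(
        self, node: TreeNode, matrix: DescriptorMatrix, idx: np.ndarray, out: np.ndarray
    ) -> None:
        if isinstance(node, Leaf):
            out[idx] = node.p_binder
            return
        col = matrix.values[idx, matrix.column_index(node.descriptor_name)]
        goes_left = col <= node.threshold
        if goes_left.any():
            self._route(node.left, matrix, idx[goes_left], out)
        if (~goes_left).any():
            self._route(node.right, matrix, idx[~goes_left], out)

    @property
    def n_nodes(self) -> int:
        return _count_nodes(self.root)

    @property
    def depth(self) -> int:
        return _height(self.root)

    def is_bare_leaf(self) -> bool:
        return isinstance(self.root, Leaf)


def _count_nodes(node: TreeNode) -> int:
    if isinstance(node, Leaf):
        return 1
    return 1 + _count_nodes(node.left) + _count_nodes(node.right)


def _height(node: TreeNode) -> int:
    if isinstance(node, Leaf):
        return 0
    return 1 + max(_height(node.left), _height(node.right))


def _collect_used(node: TreeNode, out: set) -> None:
    if isinstance(node, Split):
        out.add(node.descriptor_name)
        _collect_used(node.left, out)
        _collect_used(node.right, out)


def _subtree_counts(node: TreeNode) -> tuple[int, int]:
    if isinstance(node, Leaf):
        return node.n_binders, node.n_nonbinders
    lb, ln = _subtree_counts(node.left)
    rb, rn = _subtree_counts(node.right)
    return lb + rb, ln + rn


def _subtree_misclassified(node: TreeNode) -> int:
    if isinstance(node, Leaf):
        return node.misclassified
    return _subtree_misclassified(node.left) + _subtree_misclassified(node.right)


def gini_impurity(n_binders: int, n_nonbinders: int) -> float:
    """Two-class Gini diversity index, 1 - p1^2 - p0^2, in [0, 0.5]."""
    total = n_binders + n_nonbinders
    if total < 1:
        raise ValueError("Gini impurity of an empty node is undefined")
    p1 = n_binders / total
    p0 = n_nonbinders / total
    return 1.0 - p1 * p1 - p0 * p0


def _best_split_arrays(
    X: np.ndarray, y: np.ndarray, min_split_size: int
) -> tuple[int, float, float] | None:
    """Best (column, threshold, impurity decrease) over all midpoints.

    Returns None when the node is too small, pure, or no split decreases
    the weighted Gini impurity.  Ties resolve to the lowest column index,
    then the smallest threshold.
    """
    n = len(y)
    n1 = int(y.sum())
    if n < min_split_size or n1 == 0 or n1 == n or n < 2:
        return None
    parent = gini_impurity(n1, n - n1)

    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    ones_left = np.cumsum(ys, axis=0)[:-1].astype(float)  # (n-1, d)
    nl = np.arange(1, n, dtype=float)[:, None]
    nr = n - nl
    ones_right = n1 - ones_left
    # weighted child impurity; algebra avoids forming p twice
    gl = 1.0 - (ones_left / nl) ** 2 - ((nl - ones_left) / nl) ** 2
    gr = 1.0 - (ones_right / nr) ** 2 - ((nr - ones_right) / nr) ** 2
    decrease = parent - (nl * gl + nr * gr) / n
    valid = Xs[1:] > Xs[:-1]
    decrease[~valid] = -np.inf

    best = decrease.max()
    if not best > _MIN_DECREASE:
        return None
    cand = np.argwhere(decrease == best)  # rows (i, j)
    # lowest column index first, then smallest threshold (smallest i)
    cand = cand[np.lexsort((cand[:, 0], cand[:, 1]))]
    i, j = int(cand[0, 0]), int(cand[0, 1])
    threshold = float((Xs[i, j] + Xs[i + 1, j]) / 2.0)
    return j, threshold, float(best)


def best_split(
    data: Dataset,
    candidate_descriptors: Sequence[str],
    min_split_size: int,
) -> tuple[str, float, float] | None:
    """Best single split of a labeled dataset over the candidate descriptors.

    Candidates are scanned in the dataset's column order regardless of the
    order given.  Returns (descriptor_name, threshold, gini decrease) or
    None when no admissible split exists.
    """
    if data.labels is None:
        raise ValueError("best_split requires labeled data")
    if data.n_chemicals == 0:
        raise ValueError("best_split requires at least one row")
    cand = set(candidate_descriptors)
    if not cand:
        raise ValueError("candidate descriptor set is empty")
    names = [n for n in data.descriptors.descriptor_names if n in cand]
    cols = [data.descriptors.column_index(n) for n in names]
    res = _best_split_arrays(
        data.descriptors.values[:, cols], data.labels.labels, min_split_size
    )
    if res is None:
        return None
    j, threshold, dec = res
    return names[j], threshold, dec


def grow_tree(
    data: Dataset,
    candidate_descriptors: Sequence[str],
    config: TreeFitConfig = TreeFitConfig(),
) -> DecisionTree:
    """Recursively grow an (unpruned) tree on the candidate descriptors."""
    if data.labels is None:
        raise ValueError("grow_tree requires labeled data")
    cand = set(candidate_descriptors)
    if not cand:
        raise ValueError("candidate descriptor set is empty")
    unknown = cand - set(data.descriptors.descriptor_names)
    if unknown:
        raise KeyError(f"candidate descriptors not in data: {sorted(unknown)}")
    names = [n for n in data.descriptors.descriptor_names if n in cand]
    cols = [data.descriptors.column_index(n) for n in names]
    X = data.descriptors.values[:, cols]
    y = data.labels.labels

    def rec(idx: np.ndarray) -> TreeNode:
        yi = y[idx]
        nb = int(yi.sum())
        res = _best_split_arrays(X[idx], yi, config.min_split_size)
        if res is None:
            return Leaf(nb, len(idx) - nb)
        j, threshold, _ = res
        goes_left = X[idx, j] <= threshold
        return Split(
            names[j], threshold, rec(idx[goes_left]), rec(idx[~goes_left])
        )

    root = rec(np.arange(data.n_chemicals))
    used: set = set()
    _collect_used(root, used)
    return DecisionTree(root, frozenset(used), _subtree_misclassified(root))


def prune_tree(
    t: DecisionTree,
    data: Dataset | None = None,
    config: TreeFitConfig = TreeFitConfig(),
) -> DecisionTree:
    """Collapse bottom-level subtrees to minimize training misclassification.

    Only splits whose subtree height (in the tree as grown) is at most
    ``config.max_prune_levels`` are candidates, so pruning never removes
    more than that many levels.  Among all admissible pruned trees,
    including the unpruned one, the tree with the fewest misclassified
    training compounds wins; ties go to the tree with fewer nodes.  Leaf
    class counts already summarize the training data, so ``data`` is not
    consulted.
    """

    def rec(node: TreeNode) -> tuple[TreeNode, int, int]:
        if isinstance(node, Leaf):
            return node, node.misclassified, 1
        left, ml, cl = rec(node.left)
        right, mr, cr = rec(node.right)
        kept = Split(node.descriptor_name, node.threshold, left, right)
        m_kept, c_kept = ml + mr, 1 + cl + cr
        if _height(node) <= config.max_prune_levels:
            nb, nn = _subtree_counts(node)
            leaf = Leaf(nb, nn)
            if leaf.misclassified <= m_kept:  # tie -> smaller tree
                return leaf, leaf.misclassified, 1
        return kept, m_kept, c_kept

    root, miscl, _ = rec(t.root)
    used: set = set()
    _collect_used(root, used)
    return DecisionTree(root, frozenset(used), miscl)


def fit_tree(
    data: Dataset,
    candidate_descriptors: Sequence[str],
    config: TreeFitConfig = TreeFitConfig(),
) -> DecisionTree:
    """Grow then prune, the full single-tree fitting procedure."""
    return prune_tree(grow_tree(data, candidate_descriptors, config), data, config)


def tree_predict(t: DecisionTree, row: Mapping[str, float]) -> float:
    """Route one chemical down the tree; returns the leaf's binder proportion."""
    node = t.root
    while isinstance(node, Split):
        if node.descriptor_name not in row:
            raise KeyError(
                f"row lacks descriptor {node.descriptor_name!r} required by the tree"
            )
        v = float(row[node.descriptor_name])
        node = node.left if v <= node.threshold else node.right
    return node.p_binder


def node_to_dict(node: TreeNode) -> dict:
    if isinstance(node, Leaf):
        return {
            "kind": "leaf",
            "n_binders": node.n_binders,
            "n_nonbinders": node.n_nonbinders,
        }
    return {
        "kind": "split",
        "descriptor_name": node.descriptor_name,
        "threshold": node.threshold,
        "left": node_to_dict(node.left),
        "right": node_to_dict(node.right),
    }


def node_from_dict(d: dict) -> TreeNode:
    if d["kind"] == "leaf":
        return Leaf(int(d["n_binders"]), int(d["n_nonbinders"]))
    return Split(
        str(d["descriptor_name"]),
        float(d["threshold"]),
        node_from_dict(d["left"]),
        node_from_dict(d["right"]),
    )


def tree_to_dict(t: DecisionTree) -> dict:
    return {
        "root": node_to_dict(t.root),
        "training_misclassified": t.training_misclassified,
    }


def tree_from_dict(d: dict) -> DecisionTree:
    root = node_from_dict(d["root"])
    used: set = set()
    _collect_used(root, used)
    return DecisionTree(root, frozenset(used), int(d["training_misclassified"]))
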