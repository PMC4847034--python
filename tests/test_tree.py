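import numpy as np
import pytest

from qsarforest import (
    Leaf,
    Split,
    TreeFitConfig,
    best_split,
    fit_tree,
    gini_impurity,
    grow_tree,
    prune_tree,
    tree_predict,
)
from qsarforest.tree import (
    _height,
    _subtree_counts,
    tree_from_dict,
    tree_to_dict,
)

from conftest import make_dataset


# ---------------------------------------------------------------- oracles


def brute_force_best_split(values, labels, min_split_size):
    """Independent exhaustive search over every descriptor and midpoint.

    Same contract as best_split: maximize weighted Gini decrease, ties to
    the lowest column index then the smallest threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n < min_split_size or len(set(labels)) < 2:
        return None
    parent = gini_impurity(int(labels.sum()), int(n - labels.sum()))
    best = None
    for j in range(values.shape[1]):
        col = values[:, j]
        for lo, hi in zip(sorted(set(col))[:-1], sorted(set(col))[1:]):
            thr = (lo + hi) / 2
            left = labels[col <= thr]
            right = labels[col > thr]
            g = (
                len(left) * gini_impurity(int(left.sum()), len(left) - int(left.sum()))
                + len(right) * gini_impurity(int(right.sum()), len(right) - int(right.sum()))
            ) / n
            dec = parent - g
            if best is None or dec > best[2] + 1e-15:
                best = (j, thr, dec)
    if best is None or best[2] <= 1e-12:
        return None
    return best


def count_misclassified(tree, dataset):
    y = dataset.labels.labels
    frame = dataset.descriptors.to_frame()
    wrong = 0
    for i, (_, row) in enumerate(frame.iterrows()):
        p = tree_predict(tree, row)
        wrong += int((p >= 0.5) != y[i])
    return wrong


# ------------------------------------------------------------------ gini


@pytest.mark.parametrize(
    "nb, nn, expected",
    [(5, 5, 0.5), (10, 0, 0.0), (0, 7, 0.0), (3, 1, 0.375)],
)
def test_gini_impurity_values(nb, nn, expected):
    assert gini_impurity(nb, nn) == pytest.approx(expected)


def test_gini_empty_node_is_an_error():
    with pytest.raises(ValueError):
        gini_impurity(0, 0)


# ------------------------------------------------------------ best_split


def test_best_split_simple_threshold():
    ds = make_dataset([[1], [2], [3], [4]], [0, 0, 1, 1])
    name, thr, dec = best_split(ds, ["D1"], min_split_size=2)
    assert (name, thr) == ("D1", 2.5)
    assert dec == pytest.approx(0.5)


def test_best_split_pure_node_returns_none(separable_dataset):
    pure = separable_dataset.take_rows(range(10))  # all non-binders
    assert best_split(pure, ["D1", "D2"], min_split_size=2) is None


def test_best_split_respects_minimum_node_size():
    ds = make_dataset([[v] for v in range(9)], [0, 0, 0, 0, 1, 1, 1, 1, 1])
    assert best_split(ds, ["D1"], min_split_size=10) is None
    assert best_split(ds, ["D1"], min_split_size=9) is not None


@pytest.mark.parametrize("seed", range(8))
def test_best_split_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    n, d = rng.integers(4, 12), rng.integers(1, 5)
    values = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=(n, d))  # force ties
    labels = rng.integers(0, 2, n)
    ds = make_dataset(values, labels)
    got = best_split(ds, list(ds.descriptors.descriptor_names), 2)
    want = brute_force_best_split(values, labels, 2)
    if want is None:
        assert got is None
    else:
        j, thr, dec = want
        assert got[0] == ds.descriptors.descriptor_names[j]
        assert got[1] == pytest.approx(thr)
        assert got[2] == pytest.approx(dec)


# ------------------------------------------------------------- grow_tree


def test_grow_on_separable_data_gives_one_pure_split(separable_dataset):
    t = grow_tree(separable_dataset, ["D1", "D2"], TreeFitConfig(min_split_size=2))
    assert isinstance(t.root, Split)
    assert isinstance(t.root.left, Leaf) and isinstance(t.root.right, Leaf)
    assert t.training_misclassified == 0
    assert t.used_descriptors == {"D1"}


def test_grow_without_variation_yields_majority_leaf():
    ds = make_dataset([[1.0]] * 5, [1, 1, 1, 0, 0])
    t = grow_tree(ds, ["D1"], TreeFitConfig(min_split_size=2))
    assert isinstance(t.root, Leaf)
    assert t.root.class_label == 1
    assert t.training_misclassified == 2


def test_grow_xor_needs_at_least_three_splits(xor_dataset):
    t = grow_tree(xor_dataset, ["D1", "D2"], TreeFitConfig(min_split_size=2))
    n_splits = t.n_nodes - (t.n_nodes + 1) // 2
    assert n_splits >= 3
    assert t.training_misclassified == 0
    assert count_misclassified(t, xor_dataset) == 0


def test_grow_empty_candidate_set_is_an_error(separable_dataset):
    with pytest.raises(ValueError):
        grow_tree(separable_dataset, [], TreeFitConfig())


@pytest.mark.parametrize("seed", range(6))
def test_distinct_rows_are_always_separated(seed):
    # any instance with pairwise distinct descriptor rows is separable, so a
    # fully grown tree must reach zero training error
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(4, 13))
    values = rng.uniform(0, 1, size=(n, 3))
    labels = rng.integers(0, 2, n)
    if len(set(labels)) < 2:
        labels[0] = 1 - labels[0]
    ds = make_dataset(values, labels)
    t = grow_tree(ds, list(ds.descriptors.descriptor_names), TreeFitConfig(min_split_size=2))
    assert t.training_misclassified == 0
    assert count_misclassified(t, ds) == 0


@pytest.mark.parametrize("seed", range(4))
def test_leaf_counts_conserve_training_classes(seed):
    rng = np.random.default_rng(200 + seed)
    values = rng.uniform(0, 1, size=(30, 4))
    labels = rng.integers(0, 2, 30)
    ds = make_dataset(values, labels)
    t = grow_tree(ds, list(ds.descriptors.descriptor_names), TreeFitConfig())
    nb, nn = _subtree_counts(t.root)
    assert nb == int(labels.sum())
    assert nn == int(30 - labels.sum())
    # thresholded training predictions misclassify exactly the stored count
    assert count_misclassified(t, ds) == t.training_misclassified


def test_root_split_matches_sklearn_stump():
    sklearn_tree = pytest.importorskip("sklearn.tree")
    rng = np.random.default_rng(5)
    values = rng.uniform(0, 1, size=(40, 6))
    labels = rng.integers(0, 2, 40)
    ds = make_dataset(values, labels)
    name, thr, _ = best_split(ds, list(ds.descriptors.descriptor_names), 2)
    stump = sklearn_tree.DecisionTreeClassifier(criterion="gini", max_depth=1)
    stump.fit(values, labels)
    j = ds.descriptors.descriptor_names.index(name)
    assert stump.tree_.feature[0] == j
    # sklearn computes split thresholds in float32
    assert stump.tree_.threshold[0] == pytest.approx(thr, abs=1e-6)


# ------------------------------------------------------------ prune_tree


def test_prune_collapses_redundant_bottom_split():
    # the deepest split separates two samples the parent majority already
    # classifies correctly: same misclassification count, fewer nodes
    deep = Split(
        "D2", 0.5,
        Split("D1", 0.2, Leaf(3, 0), Leaf(2, 1)),
        Leaf(0, 5),
    )
    from qsarforest.tree import DecisionTree

    t = DecisionTree(deep, frozenset({"D1", "D2"}), 1)
    pruned = prune_tree(t, config=TreeFitConfig(max_prune_levels=3))
    assert isinstance(pruned.root.left, Leaf)
    assert pruned.training_misclassified == 1
    assert pruned.n_nodes < t.n_nodes


def test_prune_keeps_perfect_tree_intact(separable_dataset):
    t = grow_tree(separable_dataset, ["D1", "D2"], TreeFitConfig(min_split_size=2))
    pruned = prune_tree(t, separable_dataset, TreeFitConfig(min_split_size=2))
    assert tree_to_dict(pruned) == tree_to_dict(t)


def _splits_above_height(node, limit):
    out = []
    if isinstance(node, Split):
        if _height(node) > limit:
            out.append((node.descriptor_name, node.threshold))
        out += _splits_above_height(node.left, limit)
        out += _splits_above_height(node.right, limit)
    return out


@pytest.mark.parametrize("seed", range(4))
def test_pruning_is_bounded_to_bottom_levels(seed):
    rng = np.random.default_rng(300 + seed)
    values = rng.uniform(0, 1, size=(60, 5))
    labels = rng.integers(0, 2, 60)
    ds = make_dataset(values, labels)
    cfg = TreeFitConfig(min_split_size=2, max_prune_levels=3)
    grown = grow_tree(ds, list(ds.descriptors.descriptor_names), cfg)
    if grown.depth <= 3:
        pytest.skip("tree too shallow to exercise the bound")
    pruned = prune_tree(grown, ds, cfg)
    # every split sitting above the bottom 3 levels must survive pruning
    kept = set(_splits_above_height(pruned.root, 0))
    for split in _splits_above_height(grown.root, 3):
        assert split in kept
    assert pruned.training_misclassified <= grown.training_misclassified + 0


def test_prune_never_increases_misclassification(xor_dataset):
    cfg = TreeFitConfig(min_split_size=2, max_prune_levels=3)
    grown = grow_tree(xor_dataset, ["D1", "D2"], cfg)
    pruned = prune_tree(grown, xor_dataset, cfg)
    assert pruned.training_misclassified <= grown.training_misclassified
    assert count_misclassified(pruned, xor_dataset) == pruned.training_misclassified


# ---------------------------------------------------------- tree_predict


def test_single_leaf_tree_predicts_its_proportion():
    from qsarforest.tree import DecisionTree

    t = DecisionTree(Leaf(3, 2), frozenset(), 2)
    assert tree_predict(t, {}) == pytest.approx(0.6)


def test_value_equal_to_threshold_routes_left(separable_dataset):
    t = fit_tree(separable_dataset, ["D1", "D2"], TreeFitConfig(min_split_size=2))
    thr = t.root.threshold
    left_p = t.root.left.p_binder
    assert tree_predict(t, {"D1": thr, "D2": 0.5}) == pytest.approx(left_p)


def test_missing_descriptor_named_in_error(separable_dataset):
    t = fit_tree(separable_dataset, ["D1", "D2"], TreeFitConfig(min_split_size=2))
    with pytest.raises(KeyError, match="D1"):
        tree_predict(t, {"D2": 0.3})


def test_predict_matrix_agrees_with_row_prediction(xor_dataset):
    t = fit_tree(xor_dataset, ["D1", "D2"], TreeFitConfig(min_split_size=2))
    vec = t.predict_matrix(xor_dataset.descriptors)
    frame = xor_dataset.descriptors.to_frame()
    for i, (_, row) in enumerate(frame.iterrows()):
        assert vec[i] == pytest.approx(tree_predict(t, row))


def test_json_roundtrip_preserves_structure(xor_dataset):
    t = fit_tree(xor_dataset, ["D1", "D2"], TreeFitConfig(min_split_size=2))
    back = tree_from_dict(tree_to_dict(t))
    assert tree_to_dict(back) == tree_to_dict(t)
    assert back.used_descriptors == t.used_descriptors
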