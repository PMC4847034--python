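"""The Decision Forest: a consensus of trees on disjoint descriptor pools.

A Decision Forest combines a small, fixed number of decision trees (five
by default) that are forced to be heterogeneous: the first tree is fitted
on the full descriptor pool, and every descriptor it uses is removed from
the pool before the next tree is fitted.  Descriptor selection is thereby
wrapped inside model construction, and no two trees share a descriptor.

The consensus prediction for a chemical is the arithmetic mean p of the
trees' leaf binder proportions; the chemical is called a binder when
p >= 0.5.  The distance of p from the decision boundary, scaled to [0, 1],

    confidence = |p - 0.5| / 0.5,

is reported with every prediction and behaves as a reliability score:
predictions made at high confidence are empirically far more accurate
than those near the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import Dataset, DescriptorMatrix, ScalingParams, ScalingState
from .tree import (
    DecisionTree,
    TreeFitConfig,
    fit_tree,
    tree_from_dict,
    tree_to_dict,
)

__all__ = [
    "ForestFitConfig",
    "DecisionForest",
    "Prediction",
    "fit_forest",
    "forest_predict",
    "confidence_of",
    "save_forest",
    "load_forest",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestFitConfig:
    """Forest parameters; default is the canonical five-tree consensus.

    ``vote="proportion"`` averages leaf binder proportions (continuous p);
    ``vote="hard"`` averages the leaves' 0/1 class labels instead.
    """

    n_trees: int = 5
    tree: TreeFitConfig = field(default_factory=TreeFitConfig)
    vote: str = "proportion"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.vote not in ("proportion", "hard"):
            raise ValueError("vote must be 'proportion' or 'hard'")


@dataclass(frozen=True)
class Prediction:
    chemical_id: str
    p: float
    call: int
    confidence: float


@dataclass
class DecisionForest:
    trees: list[DecisionTree]
    config: ForestFitConfig = field(default_factory=ForestFitConfig)
    scaling_params: ScalingParams | None = None
    expects_scaled: bool = False

    @property
    def used_descriptors_per_tree(self) -> list[frozenset]:
        return [t.used_descriptors for t in self.trees]

    @property
    def used_descriptors(self) -> frozenset:
        out: set = set()
        for t in self.trees:
            out |= t.used_descriptors
        return frozenset(out)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("a forest must contain at least one tree")
        seen: set = set()
        for t in self.trees:
            overlap = seen & t.used_descriptors
            if overlap:
                raise ValueError(
                    f"trees share descriptors, breaking heterogeneity: {sorted(overlap)}"
                )
            seen |= t.used_descriptors


def fit_forest(data: Dataset, config: ForestFitConfig = ForestFitConfig()) -> DecisionForest:
    """Fit up to ``config.n_trees`` trees on successively reduced pools.

    Tree k+1 is fitted on the descriptor pool minus everything trees
    1..k used.  Fitting stops early when the pool empties or when the next
    tree degenerates to a bare leaf (a constant tree adds no information);
    the first tree is kept even if it is a bare leaf so the forest always
    predicts something.
    """
    if data.labels is None:
        raise ValueError("fit_forest requires labeled data")
    pool = list(data.descriptors.descriptor_names)
    trees: list[DecisionTree] = []
    for _ in range(config.n_trees):
        if not pool:
            break
        t = fit_tree(data, pool, config.tree)
        if t.is_bare_leaf():
            if not trees:
                trees.append(t)
            break
        trees.append(t)
        pool = [n for n in pool if n not in t.used_descriptors]
    scaled = data.descriptors.scaling_state is ScalingState.SCALED
    return DecisionForest(
        trees,
        config,
        data.descriptors.scaling_params if scaled else None,
        expects_scaled=scaled,
    )


def confidence_of(p: float) -> float:
    """Prediction confidence |p - 0.5| / 0.5, in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"consensus probability must lie in [0, 1], got {p}")
    return abs(p - 0.5) / 0.5


def forest_predict(f: DecisionForest, rows: DescriptorMatrix) -> list[Prediction]:
    """Consensus predictions for every chemical in ``rows``.

    ``rows`` must be scaled with the forest's scaling parameters when the
    forest was trained on scaled data.
    """
    if f.expects_scaled and rows.scaling_state is not ScalingState.SCALED:
        raise ValueError(
            "forest was trained on scaled descriptors but the input is raw; "
            "apply the stored min-max scaling first"
        )
    p = forest_predict_proba(f, rows)
    return [
        Prediction(cid, float(pi), int(pi >= 0.5), confidence_of(float(pi)))
        for cid, pi in zip(rows.chemical_ids, p)
    ]


def forest_predict_proba(f: DecisionForest, rows: DescriptorMatrix) -> np.ndarray:
    """Consensus probability p per chemical (mean over trees)."""
    per_tree = np.stack([t.predict_matrix(rows) for t in f.trees])
    if f.config.vote == "hard":
        per_tree = (per_tree >= 0.5).astype(float)
    return per_tree.mean(axis=0)


def predictions_to_frame(preds: Sequence[Prediction]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chemical_id": [p.chemical_id for p in preds],
            "p": [p.p for p in preds],
            "call": [p.call for p in preds],
            "confidence": [p.confidence for p in preds],
        }
    )


def forest_to_dict(f: DecisionForest) -> dict:
    return {
        "format_version": _FORMAT_VERSION,
        "config": {
            "n_trees": f.config.n_trees,
            "vote": f.config.vote,
            "tree": {
                "min_split_size": f.config.tree.min_split_size,
                "max_prune_levels": f.config.tree.max_prune_levels,
                "split_criterion": f.config.tree.split_criterion,
            },
        },
        "expects_scaled": f.expects_scaled,
        "scaling_params": (
            None
            if f.scaling_params is None
            else {n: [lo, hi] for n, (lo, hi) in f.scaling_params.items()}
        ),
        "trees": [tree_to_dict(t) for t in f.trees],
    }


def forest_from_dict(d: dict) -> DecisionForest:
    if d.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {d.get('format_version')}")
    cfg = d["config"]
    config = ForestFitConfig(
        n_trees=int(cfg["n_trees"]),
        tree=TreeFitConfig(
            min_split_size=int(cfg["tree"]["min_split_size"]),
            max_prune_levels=int(cfg["tree"]["max_prune_levels"]),
            split_criterion=str(cfg["tree"]["split_criterion"]),
        ),
        vote=str(cfg["vote"]),
    )
    scaling = d.get("scaling_params")
    params = (
        None
        if scaling is None
        else {n: (float(lo), float(hi)) for n, (lo, hi) in scaling.items()}
    )
    return DecisionForest(
        [tree_from_dict(t) for t in d["trees"]],
        config,
        params,
        expects_scaled=bool(d["expects_scaled"]),
    )


def save_forest(f: DecisionForest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(forest_to_dict(f)))


def load_forest(path: str | Path) -> DecisionForest:
    return forest_from_dict(json.loads(Path(path).read_text()))
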