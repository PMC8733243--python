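"""The hybrid model: a binary decision tree with a neural network per node.

Growth procedure
----------------
At each node a fresh dense network is trained on the samples reaching that
node. Every sample is then routed by the network's argmax decision rule —
class-0 scores to the left child, class-1 to the right — and the candidate
split is scored by the weighted Gini impurity of the two sides. The split
is accepted only when it decreases impurity by at least
``min_impurity_decrease`` and the usual stopping rules allow it (depth
bound, minimum node size, both sides non-empty); otherwise the node becomes
a leaf labeled with its majority class (ties go to the negative class, the
overall majority in imbalanced hairpin data). Child networks re-learn from
the original features of their subset, with freshly derived seeds.

The Gini index ``1 - sum_j p_j^2`` is the split cost function: 0 for a pure
node, 0.5 for a balanced binary node. An accepted split can therefore only
ever reduce the impurity seen by its children.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import ann
from .ann import NetworkParams, NetworkSpec, TrainConfig
from .data_io import FeatureTable
from .errors import DomainError, FormatError, ShapeError, SplitError

__all__ = [
    "TreeNode",
    "GrowConfig",
    "HDNNModel",
    "gini_index",
    "evaluate_split",
    "grow_tree",
    "predict",
    "route_indices",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "hdnn-model/1"


def gini_index(class_counts: tuple[int, int]) -> float:
    """Binary Gini impurity ``1 - sum_j p_j^2`` of a (negatives, positives) pair."""
    n0, n1 = class_counts
    if n0 < 0 or n1 < 0:
        raise DomainError("class counts must be non-negative")
    total = n0 + n1
    if total == 0:
        raise DomainError("Gini index undefined for an empty node")
    p0, p1 = n0 / total, n1 / total
    return 1.0 - (p0 * p0 + p1 * p1)


def evaluate_split(
    node_samples: FeatureTable, left_idx: np.ndarray, right_idx: np.ndarray
) -> float:
    """Weighted Gini of a candidate split: ``(nL/n) g(L) + (nR/n) g(R)``."""
    left_idx = np.asarray(left_idx, dtype=np.intp)
    right_idx = np.asarray(right_idx, dtype=np.intp)
    n = node_samples.n_samples
    if len(left_idx) == 0 or len(right_idx) == 0:
        raise SplitError("both sides of a split must be non-empty")
    combined = np.sort(np.concatenate([left_idx, right_idx]))
    if len(combined) != n or not np.array_equal(combined, np.arange(n)):
        raise SplitError("left and right indices must partition the node's samples")
    y = node_samples.labels

    def counts(idx: np.ndarray) -> tuple[int, int]:
        sub = y[idx]
        return int((sub == 0).sum()), int((sub == 1).sum())

    wl = len(left_idx) / n
    wr = len(right_idx) / n
    return wl * gini_index(counts(left_idx)) + wr * gini_index(counts(right_idx))


@dataclass
class TreeNode:
    node_id: int
    depth: int
    class_counts: tuple[int, int]  # (negatives, positives) reaching the node
    gini: float
    network: Optional[NetworkParams] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    leaf_label: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_label is not None

    def validate(self) -> None:
        if self.is_leaf:
            if self.left is not None or self.right is not None or self.network is not None:
                raise DomainError("a leaf carries no children and no network")
        else:
            if self.left is None or self.right is None or self.network is None:
                raise DomainError("an internal node needs a network and two children")


@dataclass(frozen=True)
class GrowConfig:
    """Stopping rules and training budget for tree growth."""

    max_depth: int = 5
    min_samples_split: int = 20
    min_impurity_decrease: float = 1e-4
    node_train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise DomainError("max_depth must be >= 0")
        if self.min_samples_split < 2:
            raise DomainError("min_samples_split must be >= 2")
        if self.min_impurity_decrease < 0:
            raise DomainError("min_impurity_decrease must be >= 0")


@dataclass
class HDNNModel:
    root: TreeNode
    spec: NetworkSpec
    grow_config: GrowConfig
    feature_names: list[str]

    @property
    def n_internal_nodes(self) -> int:
        def count(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + count(node.left) + count(node.right)

        return count(self.root)

    @property
    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            if node.is_leaf:
                return node.depth
            return max(d(node.left), d(node.right))

        return d(self.root)


def _counts(labels: np.ndarray) -> tuple[int, int]:
    return int((labels == 0).sum()), int((labels == 1).sum())


def _majority_label(counts: tuple[int, int]) -> int:
    n0, n1 = counts
    return 1 if n1 > n0 else 0  # tie -> negative class


def _node_seed(base_seed: int, node_id: int) -> int:
    # stable per-node fan-out of the single grow seed
    return int((base_seed * 1_000_003 + node_id * 7919) % (2**31 - 1))


def grow_tree(
    table: FeatureTable, spec: NetworkSpec, config: GrowConfig
) -> HDNNModel:
    """Grow the hybrid tree on a training table.

    A single-class table is not an error: it yields a depth-0 single-leaf
    model labeled with that class. Fully deterministic for a fixed seed.
    """
    if spec.layer_sizes[0] != table.n_features:
        raise ShapeError(
            f"spec input size {spec.layer_sizes[0]} != {table.n_features} features"
        )
    counter = {"next_id": 0}

    def build(sub: FeatureTable, depth: int) -> TreeNode:
        node_id = counter["next_id"]
        counter["next_id"] += 1
        counts = _counts(sub.labels)
        g = gini_index(counts)
        node = TreeNode(node_id=node_id, depth=depth, class_counts=counts, gini=g)

        stop = (
            depth >= config.max_depth
            or sub.n_samples < config.min_samples_split
            or min(counts) == 0  # pure node
        )
        if stop:
            node.leaf_label = _majority_label(counts)
            return node

        seed = _node_seed(config.seed, node_id)
        node_cfg = TrainConfig(
            epochs=config.node_train.epochs,
            batch_size=config.node_train.batch_size,
            learning_rate=config.node_train.learning_rate,
            lam=config.node_train.lam,
            seed=seed,
        )
        params, _ = ann.train_ann(sub, spec, node_cfg)
        routed = ann.predict_ann(params, spec, sub.features)
        left_idx = np.flatnonzero(routed == 0)
        right_idx = np.flatnonzero(routed == 1)
        if len(left_idx) == 0 or len(right_idx) == 0:
            node.leaf_label = _majority_label(counts)
            return node

        weighted = evaluate_split(sub, left_idx, right_idx)
        if g - weighted < config.min_impurity_decrease:
            node.leaf_label = _majority_label(counts)
            return node

        node.network = params
        node.left = build(sub.take(left_idx), depth + 1)
        node.right = build(sub.take(right_idx), depth + 1)
        return node

    root = build(table, 0)
    return HDNNModel(
        root=root,
        spec=spec,
        grow_config=config,
        feature_names=list(table.feature_names),
    )


def _route(model: HDNNModel, X: np.ndarray) -> np.ndarray:
    """Vectorized root-to-leaf routing; returns the predicted label per row."""
    out = np.empty(X.shape[0], dtype=np.int64)

    def descend(node: TreeNode, idx: np.ndarray) -> None:
        if len(idx) == 0:
            return
        if node.is_leaf:
            out[idx] = node.leaf_label
            return
        routed = ann.predict_ann(node.network, model.spec, X[idx])
        descend(node.left, idx[routed == 0])
        descend(node.right, idx[routed == 1])

    descend(model.root, np.arange(X.shape[0]))
    return out


def predict(model: HDNNModel, table: FeatureTable) -> np.ndarray:
    """Predict labels by routing each sample root-to-leaf (no dropout)."""
    if table.n_features != len(model.feature_names):
        raise ShapeError(
            f"table has {table.n_features} features, model expects "
            f"{len(model.feature_names)}"
        )
    return _route(model, table.features)


def route_indices(model: HDNNModel, table: FeatureTable) -> dict[int, np.ndarray]:
    """Map node_id -> row indices of ``table`` reaching that node.

    Useful for auditing the partition property: children's index sets are
    disjoint and union to their parent's.
    """
    if table.n_features != len(model.feature_names):
        raise ShapeError("feature count mismatch")
    reach: dict[int, np.ndarray] = {}

    def descend(node: TreeNode, idx: np.ndarray) -> None:
        reach[node.node_id] = idx
        if node.is_leaf or len(idx) == 0:
            if not node.is_leaf:
                descend(node.left, idx)
                descend(node.right, idx)
            return
        routed = ann.predict_ann(node.network, model.spec, table.features[idx])
        descend(node.left, idx[routed == 0])
        descend(node.right, idx[routed == 1])

    descend(model.root, np.arange(table.n_samples))
    return reach


# -- serialization -------------------------------------------------------


def _params_to_doc(params: NetworkParams) -> dict:
    return {
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }


def _params_from_doc(doc: dict) -> NetworkParams:
    return NetworkParams(
        weights=[np.asarray(w, dtype=np.float64) for w in doc["weights"]],
        biases=[np.asarray(b, dtype=np.float64) for b in doc["biases"]],
    )


def _node_to_doc(node: TreeNode) -> dict:
    doc = {
        "node_id": node.node_id,
        "depth": node.depth,
        "class_counts": list(node.class_counts),
        "gini": node.gini,
        "leaf_label": node.leaf_label,
    }
    if not node.is_leaf:
        doc["network"] = _params_to_doc(node.network)
        doc["left"] = _node_to_doc(node.left)
        doc["right"] = _node_to_doc(node.right)
    return doc


def _node_from_doc(doc: dict) -> TreeNode:
    node = TreeNode(
        node_id=int(doc["node_id"]),
        depth=int(doc["depth"]),
        class_counts=(int(doc["class_counts"][0]), int(doc["class_counts"][1])),
        gini=float(doc["gini"]),
        leaf_label=None if doc["leaf_label"] is None else int(doc["leaf_label"]),
    )
    if node.leaf_label is None:
        node.network = _params_from_doc(doc["network"])
        node.left = _node_from_doc(doc["left"])
        node.right = _node_from_doc(doc["right"])
    node.validate()
    return node


def save_model(model: HDNNModel, path):
    """Serialize a model as versioned JSON (topology + per-node parameters)."""
    doc = {
        "format": MODEL_FORMAT,
        "feature_names": model.feature_names,
        "spec": {
            "layer_sizes": list(model.spec.layer_sizes),
            "dropout_after": list(model.spec.dropout_after),
            "dropout_rate": model.spec.dropout_rate,
        },
        "grow_config": {
            "max_depth": model.grow_config.max_depth,
            "min_samples_split": model.grow_config.min_samples_split,
            "min_impurity_decrease": model.grow_config.min_impurity_decrease,
            "seed": model.grow_config.seed,
            "node_train": {
                "epochs": model.grow_config.node_train.epochs,
                "batch_size": model.grow_config.node_train.batch_size,
                "learning_rate": model.grow_config.node_train.learning_rate,
                "lam": model.grow_config.node_train.lam,
                "seed": model.grow_config.node_train.seed,
            },
        },
        "tree": _node_to_doc(model.root),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def load_model(path) -> HDNNModel:
    """Load a model saved by :func:`save_model`; checks the format tag."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"not a valid model file: {path}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise FormatError(
            f"unsupported model format {doc.get('format') if isinstance(doc, dict) else doc!r}"
        )
    spec_doc = doc["spec"]
    spec = NetworkSpec(
        layer_sizes=tuple(spec_doc["layer_sizes"]),
        dropout_after=tuple(spec_doc["dropout_after"]),
        dropout_rate=float(spec_doc["dropout_rate"]),
    )
    gc = doc["grow_config"]
    config = GrowConfig(
        max_depth=int(gc["max_depth"]),
        min_samples_split=int(gc["min_samples_split"]),
        min_impurity_decrease=float(gc["min_impurity_decrease"]),
        node_train=TrainConfig(
            epochs=int(gc["node_train"]["epochs"]),
            batch_size=int(gc["node_train"]["batch_size"]),
            learning_rate=float(gc["node_train"]["learning_rate"]),
            lam=float(gc["node_train"]["lam"]),
            seed=int(gc["node_train"]["seed"]),
        ),
        seed=int(gc["seed"]),
    )
    return HDNNModel(
        root=_node_from_doc(doc["tree"]),
        spec=spec,
        grow_config=config,
        feature_names=list(doc["feature_names"]),
    )
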