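"""Random forest backend: CART-style trees on bootstrap samples.

Each tree is grown by recursive binary splitting: at every node ``mtry``
candidate attributes are drawn at random without replacement, candidate
thresholds are the midpoints between consecutive distinct sorted values,
and the (attribute, threshold) pair minimizing the children's weighted
Gini impurity is chosen. Growth stops at pure nodes or nodes of at most
``min_node_size`` instances. The forest classifies by majority vote over
its trees; vote ties go to the first class level.

The ``mtry`` default is floor(sqrt(n_attributes)), the customary
feature-subset size for classification forests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tabular import LabeledTable, TabularError, UnlabeledTable

__all__ = [
    "DecisionTree",
    "ForestModel",
    "build_tree",
    "fit_forest",
    "predict_tree",
    "predict_forest",
    "forest_votes",
    "default_mtry",
]


def default_mtry(n_attributes: int) -> int:
    return max(1, int(np.floor(np.sqrt(n_attributes))))


@dataclass
class DecisionTree:
    """A binary classification tree stored as parallel node arrays.

    For node i: ``feature[i] >= 0`` marks an internal node splitting on
    ``x[feature[i]] <= threshold[i]`` (left child ``left[i]``, right child
    ``right[i]``); ``feature[i] == -1`` marks a leaf predicting class index
    ``leaf_class[i]``. Node 0 is the root.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray
    min_node_size: int = 1

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "min_node_size": self.min_node_size,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "DecisionTree":
        return cls(
            feature=np.asarray(doc["feature"], dtype=np.int64),
            threshold=np.asarray(doc["threshold"], dtype=float),
            left=np.asarray(doc["left"], dtype=np.int64),
            right=np.asarray(doc["right"], dtype=np.int64),
            leaf_class=np.asarray(doc["leaf_class"], dtype=np.int64),
            min_node_size=int(doc["min_node_size"]),
        )


@dataclass
class ForestModel:
    """A collection of decision trees plus the majority-vote rule."""

    trees: list[DecisionTree]
    class_levels: tuple[str, str]
    attribute_names: list[str]
    mtry: int
    min_node_size: int
    seed: int
    bootstrap: bool = True

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_text(self) -> str:
        doc = {
            "model": "random_forest",
            "class_levels": list(self.class_levels),
            "attribute_names": list(self.attribute_names),
            "mtry": self.mtry,
            "min_node_size": self.min_node_size,
            "seed": self.seed,
            "bootstrap": self.bootstrap,
            "trees": [t.to_dict() for t in self.trees],
        }
        return json.dumps(doc)

    @classmethod
    def from_text(cls, text: str) -> "ForestModel":
        doc = json.loads(text)
        if doc.get("model") != "random_forest":
            raise ValueError("not a serialized random forest model")
        return cls(
            trees=[DecisionTree.from_dict(t) for t in doc["trees"]],
            class_levels=tuple(doc["class_levels"]),
            attribute_names=list(doc["attribute_names"]),
            mtry=int(doc["mtry"]),
            min_node_size=int(doc["min_node_size"]),
            seed=int(doc["seed"]),
            bootstrap=bool(doc["bootstrap"]),
        )


def _best_split(
    x_node: np.ndarray, y_node: np.ndarray, candidates: np.ndarray
) -> tuple[int, float] | None:
    """Best (attribute, threshold) among candidate attributes by Gini.

    Impurity ties are broken toward the lowest attribute index, then the
    lowest threshold. Returns None when no candidate attribute admits a
    split (all candidate columns constant on this node).
    """
    n = y_node.size
    best_gini = np.inf
    best: tuple[int, float] | None = None
    for j in np.sort(candidates):
        x = x_node[:, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = y_node[order]
        cut = np.nonzero(xs[1:] > xs[:-1])[0]  # split after these positions
        if cut.size == 0:
            continue
        ones = np.cumsum(ys)
        total1 = ones[-1]
        n_left = cut + 1
        n_right = n - n_left
        left1 = ones[cut]
        right1 = total1 - left1
        # weighted Gini of the two children, scaled by n (constant factor)
        g_left = n_left - (left1**2 + (n_left - left1) ** 2) / n_left
        g_right = n_right - (right1**2 + (n_right - right1) ** 2) / n_right
        gini = g_left + g_right
        k = int(np.argmin(gini))  # first minimum = lowest threshold
        if gini[k] < best_gini:
            best_gini = gini[k]
            pos = cut[k]
            best = (int(j), float(0.5 * (xs[pos] + xs[pos + 1])))
    return best


def build_tree(
    X: np.ndarray,
    y: np.ndarray,
    mtry: int,
    min_node_size: int,
    rng: np.random.Generator,
) -> DecisionTree:
    """Grow one tree on (X, y) with y as 0/1 class indices.

    Nodes become leaves when pure, at or below ``min_node_size`` instances,
    or when the drawn candidate attributes are all constant on the node;
    leaf labels are the node's majority class (ties to class index 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n_attr = X.shape[1]
    if not 1 <= mtry <= n_attr:
        raise ValueError(f"mtry must lie in [1, {n_attr}], got {mtry}")

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_class: list[int] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        leaf_class.append(-1)
        return len(feature) - 1

    # (node_id, row indices) worklist; depth-first, left before right
    root = new_node()
    stack: list[tuple[int, np.ndarray]] = [(root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        y_node = y[idx]
        ones = int(y_node.sum())
        pure = ones == 0 or ones == y_node.size
        split = None
        if not pure and y_node.size > min_node_size:
            candidates = rng.choice(n_attr, size=mtry, replace=False)
            split = _best_split(X[idx], y_node, candidates)
        if split is None:
            # majority label; exact tie -> first class level (index 0)
            leaf_class[node] = int(ones > y_node.size - ones)
            continue
        j, thr = split
        go_left = X[idx, j] <= thr
        feature[node] = j
        threshold[node] = thr
        lid, rid = new_node(), new_node()
        left[node], right[node] = lid, rid
        stack.append((rid, idx[~go_left]))
        stack.append((lid, idx[go_left]))

    return DecisionTree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        leaf_class=np.asarray(leaf_class, dtype=np.int64),
        min_node_size=min_node_size,
    )


def predict_tree(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    """Class indices predicted by one tree, shape (k,)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    node = np.zeros(X.shape[0], dtype=np.int64)
    active = tree.feature[node] >= 0
    while active.any():
        rows = np.nonzero(active)[0]
        cur = node[rows]
        go_left = X[rows, tree.feature[cur]] <= tree.threshold[cur]
        node[rows] = np.where(go_left, tree.left[cur], tree.right[cur])
        active = tree.feature[node] >= 0
    return tree.leaf_class[node]


def fit_forest(
    table: LabeledTable,
    n_trees: int = 500,
    mtry: int | None = None,
    min_node_size: int = 1,
    seed: int = 0,
    bootstrap: bool = True,
) -> ForestModel:
    """Fit ``n_trees`` trees, each on a bootstrap resample of the table.

    Bootstrap resamples are drawn with replacement at the size of the
    table; with ``bootstrap=False`` every tree sees the full table (only
    the per-node feature subsampling then differs between trees). The
    forest is a pure function of (table, hyperparameters, seed).
    """
    table.require_binary()
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    if mtry is None:
        mtry = default_mtry(table.n_attributes)
    if not 1 <= mtry <= table.n_attributes:
        raise ValueError(
            f"mtry must lie in [1, {table.n_attributes}], got {mtry}"
        )
    levels = table.class_levels
    y = np.asarray([levels.index(lbl) for lbl in table.labels], dtype=np.int64)
    X = table.values
    n = X.shape[0]
    trees = []
    for ss in np.random.SeedSequence(seed).spawn(n_trees):
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        trees.append(build_tree(X[idx], y[idx], mtry, min_node_size, rng))
    return ForestModel(
        trees=trees,
        class_levels=(levels[0], levels[1]),
        attribute_names=list(table.attribute_names),
        mtry=mtry,
        min_node_size=min_node_size,
        seed=int(seed),
        bootstrap=bootstrap,
    )


def _instances_matrix(model: ForestModel, instances) -> np.ndarray:
    if isinstance(instances, (UnlabeledTable, LabeledTable)):
        x = instances.values
    else:
        x = np.atleast_2d(np.asarray(instances, dtype=float))
    if x.shape[1] != len(model.attribute_names):
        raise TabularError(
            f"instance has {x.shape[1]} attributes; model expects "
            f"{len(model.attribute_names)}"
        )
    return x


def forest_votes(model: ForestModel, instances) -> np.ndarray:
    """Per-instance vote counts over the two classes, shape (k, 2).

    Rows sum to the number of trees.
    """
    x = _instances_matrix(model, instances)
    votes = np.zeros((x.shape[0], 2), dtype=np.int64)
    for tree in model.trees:
        pred = predict_tree(tree, x)
        votes[np.arange(x.shape[0]), pred] += 1
    return votes


def predict_forest(model: ForestModel, instances) -> np.ndarray:
    """Majority-vote class labels; vote ties go to the first class level."""
    votes = forest_votes(model, instances)
    idx = np.argmax(votes, axis=1)  # first max wins ties
    return np.asarray([model.class_levels[i] for i in idx], dtype=object)
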