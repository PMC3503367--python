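"""C4.5-lineage decision trees with AdaBoost.M1 boosting.

The predictor is a weighted ensemble of binary decision trees over the 29
numeric attributes.  Induction follows the classic C4.5 recipe: at each
node every attribute is scanned for binary threshold splits at midpoints
between consecutive distinct values, the split maximizing the gain ratio
(information gain / split information) among splits with positive gain and
at least ``min_cases`` weighted cases per branch is chosen, and grown trees
are simplified by pessimistic-error pruning with the standard confidence
factor of 0.25 (the binomial upper confidence bound on the leaf error).

Divergences from C4.5/C5.0, chosen for determinism and simplicity, are
documented where they occur: cases with a missing value are excluded from
the gain computation and then routed whole to the heavier branch (instead
of fractional cases), and rule-set generation is not implemented.

Boosting is AdaBoost.M1 over case weights.  Prediction ties resolve to the
negative class, and an optional misclassification cost matrix shifts the
decision toward whichever error is cheaper -- the intended use being a low
false-positive rate, since wet-lab validation of a called miRNA is costly.
"""

from __future__ import annotations

import hashlib
import json
import math
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

from .attributes import (
    ATTRIBUTE_NAMES,
    AttributeVector,
    ControlDataset,
    LABEL_MIRNA,
    LABEL_NOT_MIRNA,
)
from .errors import EmptyDatasetError, SchemaError
from .seqio import MISSING

log = logging.getLogger(__name__)

_ALPHA_CAP = math.log(1e10)  # vote weight for a zero-error tree
_EPS = 1e-12


@dataclass(frozen=True)
class TreeParams:
    min_cases: float = 2.0
    cf: float = 0.25
    max_depth: int = 32
    prune: bool = True


@dataclass(frozen=True)
class CostMatrix:
    """2x2 misclassification costs; the diagonal is zero.

    ``fp_cost``: cost of predicting miRNA for a non-miRNA (false positive).
    ``fn_cost``: cost of predicting non-miRNA for a true miRNA.
    """

    fp_cost: float = 1.0
    fn_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.fp_cost < 0 or self.fn_cost < 0:
            raise ValueError("costs must be non-negative")


@dataclass
class TreeNode:
    """Internal node (attribute/threshold/branches) or leaf (class)."""

    # internal fields
    attribute: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # cases with value <= threshold
    right: "TreeNode | None" = None
    missing_route: str = "left"  # heavier training branch
    # leaf fields
    klass: int | None = None  # 1 = miRNA, 0 = not_miRNA
    class_weights: tuple[float, float] = (0.0, 0.0)  # (not, mi)
    training_count: float = 0.0
    error_count: float = 0.0
    _pess: float | None = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": True,
                "class": int(self.klass),
                "class_weights": list(self.class_weights),
                "n": self.training_count,
                "errors": self.error_count,
            }
        return {
            "leaf": False,
            "attribute": self.attribute,
            "threshold": self.threshold,
            "missing_route": self.missing_route,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "TreeNode":
        if d["leaf"]:
            return TreeNode(
                klass=d["class"],
                class_weights=tuple(d["class_weights"]),
                training_count=d["n"],
                error_count=d["errors"],
            )
        return TreeNode(
            attribute=d["attribute"],
            threshold=d["threshold"],
            missing_route=d["missing_route"],
            left=TreeNode.from_dict(d["left"]),
            right=TreeNode.from_dict(d["right"]),
        )


@dataclass(frozen=True)
class Prediction:
    label: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence outside [0,1]")


@dataclass
class BoostedModel:
    """Weighted tree ensemble with its training metadata."""

    trees: list[tuple[TreeNode, float]]
    epsilons: list[float]
    trials_requested: int
    cost: CostMatrix
    params: TreeParams
    attr_names: tuple[str, ...] = ATTRIBUTE_NAMES
    seed: int = 0

    @property
    def trials_run(self) -> int:
        return len(self.trees)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "trials": self.trials_requested,
                "cost": [self.cost.fp_cost, self.cost.fn_cost],
                "params": [
                    self.params.min_cases,
                    self.params.cf,
                    self.params.max_depth,
                    self.params.prune,
                ],
                "seed": self.seed,
                "attrs": list(self.attr_names),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Matrix conversion


def dataset_to_matrix(vectors: Sequence[AttributeVector]):
    """Vectors -> (X, y, ids); missing values become NaN, labels 1=miRNA."""
    n = len(vectors)
    X = np.full((n, len(ATTRIBUTE_NAMES)), np.nan)
    y = np.zeros(n, dtype=np.int8)
    ids = []
    for i, v in enumerate(vectors):
        for j, name in enumerate(ATTRIBUTE_NAMES):
            val = v.values[name]
            if val is not MISSING:
                X[i, j] = val
        y[i] = 1 if v.label == LABEL_MIRNA else 0
        ids.append(v.id)
    return X, y, ids


def _entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def build_sort_cache(X: np.ndarray) -> np.ndarray:
    """Presorted row indices per attribute column (NaN rows last).

    Sorting does not depend on case weights or on fold membership, so one
    cache serves every tree of every boosting trial of every
    cross-validation fold over the same attribute matrix.
    """
    return np.ascontiguousarray(
        np.stack([np.argsort(X[:, a], kind="stable") for a in range(X.shape[1])])
    )


def _best_split(X, y, w, mask, orders, min_cases):
    """Best gain-ratio split at this node, or None.

    Missing values are left out of the gain computation.  Ties: higher
    gain, then lower attribute index, then lower threshold.  The scan runs
    in a compiled kernel (see :func:`plantmir._dp.best_split_kernel`).
    """
    from . import _dp

    attr, thr, ratio, gain = _dp.best_split_kernel(
        X, y, w, orders, mask, min_cases
    )
    if attr < 0:
        return None
    return int(attr), float(thr), float(ratio), float(gain)


def _make_leaf(y, w, mask) -> TreeNode:
    w1 = float(w[mask & (y == 1)].sum())
    w0 = float(w[mask].sum() - w1)
    klass = 1 if w1 > w0 else 0  # tie -> not_miRNA
    return TreeNode(
        klass=klass,
        class_weights=(w0, w1),
        training_count=w0 + w1,
        error_count=min(w0, w1),
    )


def _pessimistic_errors(n: float, e: float, cf: float) -> float:
    """C4.5's predicted error count: n times the binomial upper confidence
    bound on the error rate at confidence factor cf (Clopper-Pearson upper
    limit; for e=0 this reduces to n * (1 - cf**(1/n)))."""
    if n <= 0:
        return 0.0
    if e >= n:
        return n
    upper = float(special.betaincinv(e + 1.0, n - e, 1.0 - cf))
    return n * upper


def _subtree_pessimistic(node: TreeNode, cf: float) -> float:
    """Sum of the leaves' pessimistic error counts, memoized per node
    (the tree is immutable once grown)."""
    if node._pess is None:
        if node.is_leaf:
            node._pess = _pessimistic_errors(node.training_count, node.error_count, cf)
        else:
            node._pess = _subtree_pessimistic(node.left, cf) + _subtree_pessimistic(
                node.right, cf
            )
    return node._pess


_ATTR_INDEX = {name: i for i, name in enumerate(ATTRIBUTE_NAMES)}


def induce_tree(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    params: TreeParams = TreeParams(),
    mask: np.ndarray | None = None,
    sort_cache: np.ndarray | None = None,
) -> TreeNode:
    """Grow (and prune) one decision tree on the weighted dataset.

    ``mask`` restricts training to a row subset of X (used by
    cross-validation, which shares one presorted ``sort_cache`` over all
    folds; see :func:`build_sort_cache`).
    """
    n = len(y)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    if n == 0 or not mask.any():
        raise EmptyDatasetError("cannot train on an empty dataset")
    if w is None:
        w = np.ones(n)
    if (w[mask] <= 0).any():
        raise ValueError("case weights must be positive")
    if sort_cache is None:
        sort_cache = build_sort_cache(X)
    X = np.ascontiguousarray(X)
    y = np.ascontiguousarray(y, dtype=np.int8)
    w = np.ascontiguousarray(w, dtype=np.float64)

    def grow(node_mask: np.ndarray, depth: int) -> TreeNode:
        ysub = y[node_mask]
        if depth >= params.max_depth or (ysub == ysub[0]).all():
            return _make_leaf(y, w, node_mask)
        split = _best_split(X, y, w, node_mask, sort_cache, params.min_cases)
        if split is None:
            return _make_leaf(y, w, node_mask)
        a, thr, _ratio, _gain = split
        col = X[:, a]
        known = ~np.isnan(col)
        left_mask = node_mask & known & (col <= thr)
        right_mask = node_mask & known & (col > thr)
        # route missing to the heavier branch (by weight); tie -> left
        route = "left" if w[left_mask].sum() >= w[right_mask].sum() else "right"
        miss_mask = node_mask & ~known
        if route == "left":
            left_mask = left_mask | miss_mask
        else:
            right_mask = right_mask | miss_mask
        if not left_mask.any() or not right_mask.any():  # pragma: no cover
            return _make_leaf(y, w, node_mask)
        node = TreeNode(
            attribute=ATTRIBUTE_NAMES[a],
            threshold=thr,
            missing_route=route,
            left=grow(left_mask, depth + 1),
            right=grow(right_mask, depth + 1),
        )
        if params.prune:
            as_leaf = _make_leaf(y, w, node_mask)
            leaf_err = _pessimistic_errors(
                as_leaf.training_count, as_leaf.error_count, params.cf
            )
            if leaf_err <= _subtree_pessimistic(node, params.cf) + 1e-9:
                return as_leaf
        return node

    return grow(mask.copy(), 0)


def apply_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    """Vectorized class assignment of every row of X by one tree."""
    out = np.zeros(len(X), dtype=np.int8)

    def walk(nd: TreeNode, mask: np.ndarray) -> None:
        if not mask.any():
            return
        if nd.is_leaf:
            out[mask] = nd.klass
            return
        a = _ATTR_INDEX[nd.attribute]
        col = X[:, a]
        known = ~np.isnan(col)
        left = mask & known & (col <= nd.threshold)
        right = mask & known & (col > nd.threshold)
        miss = mask & ~known
        if nd.missing_route == "left":
            left = left | miss
        else:
            right = right | miss
        walk(nd.left, left)
        walk(nd.right, right)

    walk(node, np.ones(len(X), dtype=bool))
    return out


def boost(
    X: np.ndarray,
    y: np.ndarray,
    trials: int = 10,
    cost: CostMatrix = CostMatrix(),
    params: TreeParams = TreeParams(),
    seed: int = 0,
    mask: np.ndarray | None = None,
    sort_cache: np.ndarray | None = None,
) -> BoostedModel:
    """AdaBoost.M1 over C4.5-style trees.

    Case weights start uniform.  A trial with zero weighted error keeps its
    tree at a capped vote weight and stops; a trial with weighted error
    >= 0.5 is discarded and boosting stops (except that a first such tree
    is kept at unit weight so the model is never empty).  Otherwise the
    vote weight is ln((1-eps)/eps) and misclassified cases are up-weighted.
    Induction itself is deterministic; the seed is recorded metadata.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    n = len(y)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    n_train = int(mask.sum())
    if n == 0 or n_train == 0:
        raise EmptyDatasetError("cannot train on an empty dataset")
    if sort_cache is None:
        sort_cache = build_sort_cache(X)
    members = np.nonzero(mask)[0]
    Xm = np.ascontiguousarray(X[members])
    ym = y[members]
    w = np.zeros(n)
    w[members] = 1.0
    trees: list[tuple[TreeNode, float]] = []
    epsilons: list[float] = []
    for t in range(trials):
        tree = induce_tree(X, y, w, params, mask=mask, sort_cache=sort_cache)
        pred = apply_tree(tree, Xm)
        miss = pred != ym
        eps = float(w[members][miss].sum() / w[members].sum())
        if eps <= _EPS:
            trees.append((tree, _ALPHA_CAP))
            epsilons.append(0.0)
            break
        if eps >= 0.5:
            if not trees:
                trees.append((tree, 1.0))
                epsilons.append(eps)
            break
        alpha = math.log((1.0 - eps) / eps)
        trees.append((tree, alpha))
        epsilons.append(eps)
        wm = w[members] * np.exp(alpha * miss)
        w[members] = wm * (n_train / wm.sum())
    return BoostedModel(
        trees=trees,
        epsilons=epsilons,
        trials_requested=trials,
        cost=cost,
        params=params,
        seed=seed,
    )


def _vote_share(model: BoostedModel, votes_mi: float) -> float:
    total = sum(alpha for _, alpha in model.trees)
    return votes_mi / total if total > 0 else 0.0


def _decide(p_mi: float, cost: CostMatrix) -> int:
    """Minimize expected cost; ties go to not_miRNA."""
    exp_cost_mi = (1.0 - p_mi) * cost.fp_cost
    exp_cost_not = p_mi * cost.fn_cost
    return 1 if exp_cost_mi < exp_cost_not else 0


def predict_matrix(model: BoostedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, p_miRNA) for every row of X."""
    votes = np.zeros(len(X))
    for tree, alpha in model.trees:
        votes += alpha * apply_tree(tree, X)
    total = sum(alpha for _, alpha in model.trees)
    p_mi = votes / total if total > 0 else np.zeros(len(X))
    labels = np.array([_decide(p, model.cost) for p in p_mi], dtype=np.int8)
    return labels, p_mi


def predict(model: BoostedModel, vector: AttributeVector | dict) -> Prediction:
    """Classify one attribute vector; confidence is the predicted class's
    share of the total vote weight."""
    values = vector.values if isinstance(vector, AttributeVector) else vector
    if set(values) != set(model.attr_names):
        raise SchemaError("attribute names do not match the model schema")
    row = np.full((1, len(model.attr_names)), np.nan)
    for j, name in enumerate(model.attr_names):
        if values[name] is not MISSING:
            row[0, j] = values[name]
    labels, p_mi = predict_matrix(model, row)
    label = LABEL_MIRNA if labels[0] == 1 else LABEL_NOT_MIRNA
    confidence = float(p_mi[0] if labels[0] == 1 else 1.0 - p_mi[0])
    return Prediction(label=label, confidence=confidence)


# ---------------------------------------------------------------------------
# Attribute reporting


def attribute_usage(model: BoostedModel, X: np.ndarray) -> dict[str, float]:
    """Percent of cases whose root-to-leaf path, in any ensemble tree,
    tests each attribute."""
    n = len(X)
    used = {name: np.zeros(n, dtype=bool) for name in model.attr_names}
    names = list(model.attr_names)

    def walk(nd: TreeNode, mask: np.ndarray) -> None:
        if nd.is_leaf or not mask.any():
            return
        used[nd.attribute][mask] = True
        a = names.index(nd.attribute)
        col = X[:, a]
        known = ~np.isnan(col)
        left = mask & known & (col <= nd.threshold)
        right = mask & known & (col > nd.threshold)
        miss = mask & ~known
        if nd.missing_route == "left":
            left = left | miss
        else:
            right = right | miss
        walk(nd.left, left)
        walk(nd.right, right)

    for tree, _alpha in model.trees:
        walk(tree, np.ones(n, dtype=bool))
    return {name: 100.0 * used[name].sum() / n for name in model.attr_names}


def winnow_importance(
    X: np.ndarray,
    y: np.ndarray,
    trials: int = 10,
    cost: CostMatrix = CostMatrix(),
    params: TreeParams = TreeParams(),
    seed: int = 0,
) -> dict[str, float]:
    """Leave-one-attribute-out importance.

    For each attribute the model is retrained with that attribute withheld
    (its column treated as entirely missing) and the increase in training
    error rate, in percentage points, is reported.  An admittedly imperfect
    measure -- attributes carrying redundant signal score low -- but a
    useful overall view of discriminative power.  Covers all attributes.
    """
    full = boost(X, y, trials, cost, params, seed)
    labels, _ = predict_matrix(full, X)
    err_full = float((labels != y).mean())
    out: dict[str, float] = {}
    for j, name in enumerate(ATTRIBUTE_NAMES):
        Xj = X.copy()
        Xj[:, j] = np.nan
        m = boost(Xj, y, trials, cost, params, seed)
        lab, _ = predict_matrix(m, Xj)
        err = float((lab != y).mean())
        out[name] = 100.0 * (err - err_full)
    return out


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: BoostedModel, path) -> None:
    doc = {
        "format": "plantmir-boosted-trees/1",
        "attributes": list(model.attr_names),
        "trees": [
            {"tree": tree.to_dict(), "vote_weight": alpha}
            for tree, alpha in model.trees
        ],
        "epsilons": model.epsilons,
        "trials_requested": model.trials_requested,
        "cost": {"fp": model.cost.fp_cost, "fn": model.cost.fn_cost},
        "params": {
            "min_cases": model.params.min_cases,
            "cf": model.params.cf,
            "max_depth": model.params.max_depth,
            "prune": model.params.prune,
        },
        "seed": model.seed,
        "config_hash": model.config_hash,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path) -> BoostedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "plantmir-boosted-trees/1":
        raise ValueError(f"{path}: not a plantmir model file")
    return BoostedModel(
        trees=[
            (TreeNode.from_dict(t["tree"]), t["vote_weight"]) for t in doc["trees"]
        ],
        epsilons=doc["epsilons"],
        trials_requested=doc["trials_requested"],
        cost=CostMatrix(fp_cost=doc["cost"]["fp"], fn_cost=doc["cost"]["fn"]),
        params=TreeParams(**doc["params"]),
        attr_names=tuple(doc["attributes"]),
        seed=doc["seed"],
    )
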