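"""Joint regression/classification random forest with tree-weighted aggregation.

Each tree is a weighted regression tree grown on a bootstrap sample: split
quality is weighted variance reduction, i.e. the weighted node MSE
improvement with ancestor/child node weights given by the members' total
importance mass. Tree construction is delegated to sklearn's
``DecisionTreeRegressor`` (whose impurity-decrease criterion is exactly this
quantity when given the initial sample weights); everything the joint model
adds is implemented here:

* leaves are annotated with their bootstrap members' weighted mean response,
  their majority class by importance mass (ties resistant; reduces to raw
  counts under uniform weights) and the per-class mass needed by the
  majority weighting scheme;
* the forest classifies by majority vote over per-tree leaf classes
  (ties resistant);
* the continuous prediction is a tree-weighted average of the reached
  leaves' means under one of five schemes: ``uniform`` (1/B, the
  conventional regression forest), ``binary`` (only trees agreeing with the
  forest vote count, equally), ``binary_sens`` (binary for
  sensitive-predicted queries, uniform otherwise), ``majority`` (trees
  weighted by the weighted fraction of reached-leaf members whose class
  agrees with the forest vote) and ``majority_sens`` (majority for
  sensitive-predicted queries, uniform otherwise).

Fitted forests serialize to a documented JSON structure and predictions
replay bit-identically from the deserialized model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .datasets import Dataset
from .imbalance import SampleWeights, uniform_sample_weights

TreeWeighting = Literal["uniform", "binary", "binary_sens", "majority", "majority_sens"]

_SCHEMES = ("uniform", "binary", "binary_sens", "majority", "majority_sens")

RESISTANT, SENSITIVE = 0, 1


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``m`` is the number of features drawn without replacement at each
    split (default ⌊P/3⌋, the regression-forest convention), ``B`` the
    number of trees, ``min_samples_leaf`` the growth-stopping leaf size.
    """

    B: int = 500
    m: int | None = None
    min_samples_leaf: int = 5
    seed: int = 0
    tree_weighting: TreeWeighting = "binary_sens"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.tree_weighting not in _SCHEMES:
            raise ValueError(f"unknown tree weighting scheme: {self.tree_weighting!r}")

    def resolve_m(self, n_features: int) -> int:
        m = self.m if self.m is not None else max(1, n_features // 3)
        if not 1 <= m <= n_features:
            raise ValueError(f"m={m} out of range for P={n_features}")
        return m


@dataclass
class AnnotatedTree:
    """A regression tree plus per-leaf class and weight-mass annotations.

    Node arrays follow the sklearn layout: ``children_left[v] == -1`` marks
    a leaf; internal node ``v`` sends ``x[feature[v]] <= threshold[v]``
    left. Leaf annotations are indexed by node id and only meaningful at
    leaves: ``leaf_value`` is the w*-weighted mean response of the leaf's
    bootstrap members, ``leaf_class`` the class with the larger member
    importance mass (ties resistant), ``mass[c]`` the total w* of members
    with class ``c`` (also the numerator data of the majority weighting
    scheme), ``count[c]`` the raw member counts.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_value: np.ndarray
    leaf_class: np.ndarray
    mass0: np.ndarray
    mass1: np.ndarray
    count0: np.ndarray
    count1: np.ndarray
    bootstrap_idx: np.ndarray
    importances: np.ndarray  # unnormalized per-feature impurity decrease

    @property
    def n_nodes(self) -> int:
        return self.children_left.size

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id reached by each row of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0], dtype=int)
        for i, x in enumerate(X):
            v = 0
            while self.children_left[v] != -1:
                v = (
                    self.children_left[v]
                    if x[self.feature[v]] <= self.threshold[v]
                    else self.children_right[v]
                )
            out[i] = v
        return out

    def leaf_ids(self) -> np.ndarray:
        return np.flatnonzero(self.children_left == -1)


@dataclass
class PredictionResult:
    """Joint prediction for one query sample.

    ``predicted_value`` is always the tree-weight-weighted average of the
    per-tree leaf means, so ``sum(tree_weights) == 1`` and
    ``predicted_value == tree_weights @ tree_values``.
    """

    predicted_class: int
    predicted_value: float
    tree_weights: np.ndarray
    tree_values: np.ndarray
    tree_classes: np.ndarray


class SauronForest:
    """A fitted forest of annotated trees; see the module docstring."""

    def __init__(
        self,
        trees: list[AnnotatedTree],
        params: ForestParams,
        gene_ids: list[str],
        weight_scheme: str,
    ) -> None:
        self.trees = trees
        self.params = params
        self.gene_ids = list(gene_ids)
        self.weight_scheme = weight_scheme

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return len(self.gene_ids)

    # -- classification -------------------------------------------------

    def tree_classes(self, X: np.ndarray) -> np.ndarray:
        """Per-tree leaf-class votes, shape (n_samples, B)."""
        X = self._check_X(X)
        return np.column_stack([t.leaf_class[t.apply(X)] for t in self.trees])

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """Forest class = mode of the tree votes; ties go to resistant."""
        votes = self.tree_classes(X)
        sens = votes.sum(axis=1)
        return (sens * 2 > votes.shape[1]).astype(int)

    # -- regression ------------------------------------------------------

    def tree_values(self, X: np.ndarray) -> np.ndarray:
        """Per-tree leaf mean responses, shape (n_samples, B)."""
        X = self._check_X(X)
        return np.column_stack([t.leaf_value[t.apply(X)] for t in self.trees])

    def tree_weights(
        self, X: np.ndarray, scheme: TreeWeighting | None = None
    ) -> np.ndarray:
        """Per-tree aggregation weights w_b(x'), shape (n_samples, B); rows sum to 1."""
        scheme = scheme or self.params.tree_weighting
        if scheme not in _SCHEMES:
            raise ValueError(f"unknown tree weighting scheme: {scheme!r}")
        X = self._check_X(X)
        n, B = X.shape[0], self.n_trees
        if scheme == "uniform":
            return np.full((n, B), 1.0 / B)
        votes = self.tree_classes(X)
        forest_class = (votes.sum(axis=1) * 2 > B).astype(int)
        if scheme in ("binary", "binary_sens"):
            agree = (votes == forest_class[:, None]).astype(float)
            n_agree = agree.sum(axis=1)
            assert np.all(n_agree > 0), "forest mode must agree with >= 1 tree"
            w = agree / n_agree[:, None]
        else:  # majority / majority_sens
            frac = np.empty((n, B))
            for b, t in enumerate(self.trees):
                leaves = t.apply(X)
                m0, m1 = t.mass0[leaves], t.mass1[leaves]
                agree_mass = np.where(forest_class == 1, m1, m0)
                frac[:, b] = agree_mass / (m0 + m1)
            w = frac / frac.sum(axis=1, keepdims=True)
        if scheme in ("binary_sens", "majority_sens"):
            uniform = np.full((n, B), 1.0 / B)
            w = np.where((forest_class == 1)[:, None], w, uniform)
        return w

    def predict_value(
        self, X: np.ndarray, scheme: TreeWeighting | None = None
    ) -> np.ndarray:
        """Tree-weighted continuous prediction for each row of ``X``."""
        w = self.tree_weights(X, scheme)
        return (w * self.tree_values(X)).sum(axis=1)

    def predict(
        self, X: np.ndarray, scheme: TreeWeighting | None = None
    ) -> list[PredictionResult]:
        """Full per-sample prediction records (class, value, per-tree detail)."""
        X = self._check_X(X)
        votes = self.tree_classes(X)
        classes = (votes.sum(axis=1) * 2 > self.n_trees).astype(int)
        weights = self.tree_weights(X, scheme)
        values = self.tree_values(X)
        preds = (weights * values).sum(axis=1)
        return [
            PredictionResult(
                predicted_class=int(classes[i]),
                predicted_value=float(preds[i]),
                tree_weights=weights[i],
                tree_values=values[i],
                tree_classes=votes[i],
            )
            for i in range(X.shape[0])
        ]

    def feature_importances(self) -> np.ndarray:
        """Total weighted impurity decrease per gene, normalized to sum 1."""
        total = np.sum([t.importances for t in self.trees], axis=0)
        s = total.sum()
        return total / s if s > 0 else total

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "sauronrf-forest-v1",
            "params": {
                "B": self.params.B,
                "m": self.params.m,
                "min_samples_leaf": self.params.min_samples_leaf,
                "seed": self.params.seed,
                "tree_weighting": self.params.tree_weighting,
            },
            "gene_ids": self.gene_ids,
            "weight_scheme": self.weight_scheme,
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "leaf_value": t.leaf_value.tolist(),
                    "leaf_class": t.leaf_class.tolist(),
                    "mass0": t.mass0.tolist(),
                    "mass1": t.mass1.tolist(),
                    "count0": t.count0.tolist(),
                    "count1": t.count1.tolist(),
                    "bootstrap_idx": t.bootstrap_idx.tolist(),
                    "importances": t.importances.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SauronForest":
        if d.get("format") != "sauronrf-forest-v1":
            raise ValueError("unrecognized forest serialization format")
        params = ForestParams(**d["params"])
        trees = [
            AnnotatedTree(
                children_left=np.array(t["children_left"], dtype=int),
                children_right=np.array(t["children_right"], dtype=int),
                feature=np.array(t["feature"], dtype=int),
                threshold=np.array(t["threshold"], dtype=float),
                leaf_value=np.array(t["leaf_value"], dtype=float),
                leaf_class=np.array(t["leaf_class"], dtype=int),
                mass0=np.array(t["mass0"], dtype=float),
                mass1=np.array(t["mass1"], dtype=float),
                count0=np.array(t["count0"], dtype=int),
                count1=np.array(t["count1"], dtype=int),
                bootstrap_idx=np.array(t["bootstrap_idx"], dtype=int),
                importances=np.array(t["importances"], dtype=float),
            )
            for t in d["trees"]
        ]
        return cls(trees, params, d["gene_ids"], d["weight_scheme"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SauronForest":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"query has {X.shape[1]} features, forest expects {self.n_features}"
            )
        return X


def annotate_tree(
    children_left: np.ndarray,
    children_right: np.ndarray,
    feature: np.ndarray,
    threshold: np.ndarray,
    leaf_of_member: np.ndarray,
    y_members: np.ndarray,
    Y_members: np.ndarray,
    w_members: np.ndarray,
    bootstrap_idx: np.ndarray,
    importances: np.ndarray,
) -> AnnotatedTree:
    """Build leaf annotations from a tree structure and its bootstrap members."""
    n_nodes = children_left.size
    leaf_value = np.zeros(n_nodes)
    mass0 = np.zeros(n_nodes)
    mass1 = np.zeros(n_nodes)
    count0 = np.zeros(n_nodes, dtype=int)
    count1 = np.zeros(n_nodes, dtype=int)
    wsum = np.bincount(leaf_of_member, weights=w_members, minlength=n_nodes)
    wysum = np.bincount(leaf_of_member, weights=w_members * y_members, minlength=n_nodes)
    occupied = wsum > 0
    leaf_value[occupied] = wysum[occupied] / wsum[occupied]
    sens = Y_members == 1
    mass1[:] = np.bincount(leaf_of_member[sens], weights=w_members[sens], minlength=n_nodes)
    mass0[:] = np.bincount(leaf_of_member[~sens], weights=w_members[~sens], minlength=n_nodes)
    count1[:] = np.bincount(leaf_of_member[sens], minlength=n_nodes)
    count0[:] = np.bincount(leaf_of_member[~sens], minlength=n_nodes)
    # majority by importance mass (reduces to raw counts under uniform
    # weights, and counts upsampled duplicates with their multiplicity);
    # ties -> resistant
    leaf_class = (mass1 > mass0).astype(int)
    return AnnotatedTree(
        children_left=children_left,
        children_right=children_right,
        feature=feature,
        threshold=threshold,
        leaf_value=leaf_value,
        leaf_class=leaf_class,
        mass0=mass0,
        mass1=mass1,
        count0=count0,
        count1=count1,
        bootstrap_idx=bootstrap_idx,
        importances=importances,
    )


def fit(
    ds: Dataset,
    weights: SampleWeights | None = None,
    params: ForestParams = ForestParams(),
) -> SauronForest:
    """Fit a joint regression/classification forest.

    Each of the B trees is grown on an N-sized bootstrap drawn with
    replacement from the training samples; at each split m features are
    drawn without replacement and the split minimizing the weighted child
    error (equivalently, maximizing the weighted-MSE improvement with
    importance-mass node weights) is chosen, stopping at
    ``min_samples_leaf``. Leaves are then annotated with their members'
    weighted mean response, majority class and per-class weight mass.
    """
    if weights is None:
        weights = uniform_sample_weights(ds.n_samples)
    w_star = np.asarray(weights.w_star, dtype=float)
    if w_star.size != ds.n_samples:
        raise ValueError("weights length must equal the number of samples")
    N, P = ds.n_samples, ds.n_genes
    if N < 2 * params.min_samples_leaf:
        raise ValueError(
            f"need at least {2 * params.min_samples_leaf} samples to make one split"
        )
    m = params.resolve_m(P)
    rng = np.random.default_rng(params.seed)
    trees: list[AnnotatedTree] = []
    for _ in range(params.B):
        boot = rng.integers(0, N, size=N)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        Xb, yb, Yb, wb = ds.X[boot], ds.y[boot], ds.Y[boot], w_star[boot]
        reg = DecisionTreeRegressor(
            criterion="squared_error",
            max_features=m,
            min_samples_leaf=params.min_samples_leaf,
            random_state=tree_seed,
        )
        reg.fit(Xb, yb, sample_weight=wb)
        tr = reg.tree_
        trees.append(
            annotate_tree(
                children_left=tr.children_left.copy(),
                children_right=tr.children_right.copy(),
                feature=tr.feature.copy(),
                threshold=tr.threshold.copy(),
                leaf_of_member=reg.apply(Xb),
                y_members=yb,
                Y_members=Yb,
                w_members=wb,
                bootstrap_idx=boot,
                importances=tr.compute_feature_importances(normalize=False),
            )
        )
    return SauronForest(trees, params, ds.gene_ids, weights.scheme)
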