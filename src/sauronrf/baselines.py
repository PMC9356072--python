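"""Comparator models: threshold-classifying rRF, cRF-derived regression,
and the hierarchical classify-then-regress forest.

The conventional regression forest (rRF) is a :class:`~sauronrf.forest.SauronForest`
with uniform sample weights and uniform tree weighting; its classification
is obtained by comparing the continuous prediction to the drug threshold
(:func:`rrf_classify`). The conventional classification forest (cRF) is
wrapped here with per-leaf continuous annotations so it can also produce a
continuous prediction: average the training responses in the reached leaf,
then average over the trees that agree with the forest's majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .datasets import Dataset, binarize
from .forest import ForestParams, SauronForest, fit as fit_forest
from .imbalance import uniform_sample_weights


def rrf_classify(y_pred: np.ndarray, t: float) -> np.ndarray:
    """Classify regression-forest output by the drug-specific threshold.

    Reuses the dataset binarization rule: sensitive iff prediction < t.
    """
    return binarize(y_pred, t)


@dataclass
class _ClassTree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray
    leaf_y_mean: np.ndarray  # unweighted mean of training responses per leaf

    def apply(self, X: np.ndarray) -> np.ndarray:
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


class ClassificationForest:
    """A bagged Gini classification forest whose leaves also store the
    unweighted mean continuous response of their bootstrap members.

    Tree votes use the raw-count leaf majority (ties resistant); the forest
    vote is the mode of the tree votes (ties resistant), matching the joint
    model's conventions.
    """

    def __init__(self, trees: list[_ClassTree], params: ForestParams, gene_ids: list[str]):
        self.trees = trees
        self.params = params
        self.gene_ids = list(gene_ids)

    @classmethod
    def fit(cls, ds: Dataset, params: ForestParams = ForestParams()) -> "ClassificationForest":
        if len(np.unique(ds.Y)) < 2:
            raise ValueError("classification forest needs both classes in training data")
        N, P = ds.n_samples, ds.n_genes
        m = params.resolve_m(P)
        rng = np.random.default_rng(params.seed)
        trees: list[_ClassTree] = []
        for _ in range(params.B):
            boot = rng.integers(0, N, size=N)
            tree_seed = int(rng.integers(0, 2**31 - 1))
            Xb, yb, Yb = ds.X[boot], ds.y[boot], ds.Y[boot]
            clf = DecisionTreeClassifier(
                criterion="gini",
                max_features=m,
                min_samples_leaf=params.min_samples_leaf,
                random_state=tree_seed,
            )
            clf.fit(Xb, Yb)
            leaf_of_member = clf.apply(Xb)
            n_nodes = clf.tree_.node_count
            ysum = np.bincount(leaf_of_member, weights=yb, minlength=n_nodes)
            cnt = np.bincount(leaf_of_member, minlength=n_nodes)
            leaf_y_mean = np.zeros(n_nodes)
            leaf_y_mean[cnt > 0] = ysum[cnt > 0] / cnt[cnt > 0]
            c1 = np.bincount(leaf_of_member[Yb == 1], minlength=n_nodes)
            c0 = np.bincount(leaf_of_member[Yb == 0], minlength=n_nodes)
            trees.append(
                _ClassTree(
                    children_left=clf.tree_.children_left.copy(),
                    children_right=clf.tree_.children_right.copy(),
                    feature=clf.tree_.feature.copy(),
                    threshold=clf.tree_.threshold.copy(),
                    leaf_class=(c1 > c0).astype(int),
                    leaf_y_mean=leaf_y_mean,
                )
            )
        return cls(trees, params, ds.gene_ids)

    def tree_classes(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([t.leaf_class[t.apply(X)] for t in self.trees])

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        votes = self.tree_classes(X)
        return (votes.sum(axis=1) * 2 > votes.shape[1]).astype(int)

    def tree_y_means(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([t.leaf_y_mean[t.apply(X)] for t in self.trees])


def crf_predict_value(forest: ClassificationForest, X: np.ndarray) -> np.ndarray:
    """Continuous prediction derived from a classification forest.

    For each query: find the trees whose vote agrees with the forest's
    majority vote, take each agreeing tree's reached-leaf unweighted mean
    response, and average over those trees.
    """
    votes = forest.tree_classes(X)
    forest_class = (votes.sum(axis=1) * 2 > votes.shape[1]).astype(int)
    means = forest.tree_y_means(X)
    agree = votes == forest_class[:, None]
    return (means * agree).sum(axis=1) / agree.sum(axis=1)


class HierarchicalForest:
    """Classify-then-regress baseline: one classification RF on all training
    data routes each query to one of two regression RFs trained on the
    sensitive and resistant subsets respectively."""

    def __init__(
        self,
        classifier: ClassificationForest,
        regressor_sens: SauronForest,
        regressor_res: SauronForest,
    ) -> None:
        self.classifier = classifier
        self.regressor_sens = regressor_sens
        self.regressor_res = regressor_res

    @classmethod
    def fit(cls, ds: Dataset, params: ForestParams = ForestParams()) -> "HierarchicalForest":
        counts = ds.class_counts()
        if counts.n_sens == 0 or counts.n_res == 0:
            raise ValueError("both classes must be present in training data")
        clf = ClassificationForest.fit(ds, params)
        subsets = {}
        for name, cls_label in (("sensitive", 1), ("resistant", 0)):
            idx = np.flatnonzero(ds.Y == cls_label)
            if idx.size < 2 * params.min_samples_leaf:
                raise ValueError(
                    f"too few {name} samples ({idx.size}) to fit the "
                    f"{name}-class regressor"
                )
            sub = ds.subset(idx)
            subsets[name] = fit_forest(
                sub,
                uniform_sample_weights(sub.n_samples),
                ForestParams(
                    B=params.B,
                    m=params.m,
                    min_samples_leaf=params.min_samples_leaf,
                    seed=params.seed,
                    tree_weighting="uniform",
                ),
            )
        return cls(clf, subsets["sensitive"], subsets["resistant"])

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict_class(X)

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cls = self.predict_class(X)
        out = np.empty(X.shape[0])
        for label, reg in ((1, self.regressor_sens), (0, self.regressor_res)):
            mask = cls == label
            if mask.any():
                out[mask] = reg.predict_value(X[mask], scheme="uniform")
        return out
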