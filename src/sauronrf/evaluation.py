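"""Metrics and the train/test + cross-validation experiment workflow.

Classification quality is summarized by sensitivity, specificity and
Matthews correlation coefficient (MCC); regression quality by MSE and
median squared error, reported overall and separately for the sensitive
and resistant subsets (defined by the *true* labels), since overall MSE on
imbalanced data hides poor minority-class regression.

:func:`run_experiment` reproduces the standard protocol: a seeded 80/20
train/test split drawn without replacement, 5-fold CV on the training part
over a hyperparameter grid (feature selection refit inside every fold),
final refit on the whole training set and a held-out test report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold

from .datasets import Dataset
from .feature_selection import greedy_mrmr
from .forest import ForestParams, TreeWeighting, fit as fit_forest
from .imbalance import (
    SampleWeights,
    distance_sample_weights,
    proportional_upsample,
    simple_sample_weights,
    uniform_sample_weights,
    upsample,
)
from .baselines import ClassificationForest, HierarchicalForest, crf_predict_value, rrf_classify

logger = logging.getLogger(__name__)

ModelKind = Literal["rrf", "harf", "sauron", "crf", "hierarchical"]
Resampling = Literal["none", "upsample", "proportional"]


@dataclass(frozen=True)
class EvaluationReport:
    """Joint regression/classification test report.

    Per-class regression metrics are NaN when the class is absent from the
    evaluated samples.
    """

    mse_all: float
    mse_sens: float
    mse_res: float
    medse_all: float
    medse_sens: float
    medse_res: float
    sensitivity: float
    specificity: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return asdict(self)


def classification_metrics(Y_true: np.ndarray, Y_pred: np.ndarray) -> dict:
    """Confusion counts, sensitivity, specificity and MCC.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as
    0 when any factor of the denominator vanishes. Sensitivity/specificity
    are NaN when their class is absent.
    """
    Y_true = np.asarray(Y_true, dtype=int)
    Y_pred = np.asarray(Y_pred, dtype=int)
    if Y_true.shape != Y_pred.shape or Y_true.size == 0:
        raise ValueError("Y_true and Y_pred must be non-empty and equal-length")
    tn, fp, fn, tp = confusion_matrix(Y_true, Y_pred, labels=[0, 1]).ravel()
    tp, fp, tn, fn = int(tp), int(fp), int(tn), int(fn)
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom2) if denom2 > 0 else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "mcc": float(mcc),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def regression_metrics_per_class(
    y_true: np.ndarray, y_pred: np.ndarray, Y_true: np.ndarray
) -> dict:
    """MSE and median squared error, overall and per true class (NaN if empty)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    Y_true = np.asarray(Y_true, dtype=int)
    if not (y_true.shape == y_pred.shape == Y_true.shape):
        raise ValueError("length mismatch")
    se = (y_true - y_pred) ** 2
    out = {"mse_all": float(se.mean()), "medse_all": float(np.median(se))}
    for name, cls in (("sens", 1), ("res", 0)):
        sub = se[Y_true == cls]
        out[f"mse_{name}"] = float(sub.mean()) if sub.size else float("nan")
        out[f"medse_{name}"] = float(np.median(sub)) if sub.size else float("nan")
    return out


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    Y_true: np.ndarray,
    Y_pred: np.ndarray,
) -> EvaluationReport:
    """Combine the classification and per-class regression metrics."""
    return EvaluationReport(
        **regression_metrics_per_class(y_true, y_pred, Y_true),
        **classification_metrics(Y_true, Y_pred),
    )


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit and how it counters imbalance.

    ``rrf`` — conventional regression forest; classifies by comparing the
    continuous prediction to the threshold. ``harf`` — regression forest
    with class-annotated leaves and binary tree weighting. ``sauron`` —
    the joint model with any sample-weight/resampling scheme and any tree
    weighting. ``crf`` — conventional classification forest with a derived
    continuous prediction. ``hierarchical`` — classify-then-regress.
    """

    kind: ModelKind = "sauron"
    sample_weighting: Literal["uniform", "simple", "linear", "quadratic"] = "uniform"
    resampling: Resampling = "none"
    tree_weighting: TreeWeighting = "binary_sens"

    def __post_init__(self) -> None:
        if self.resampling != "none" and self.sample_weighting != "uniform":
            raise ValueError("combine either sample weights or resampling, not both")

    @property
    def classifies_by_vote(self) -> bool:
        return self.kind in ("harf", "sauron", "crf", "hierarchical")


def _make_weights(spec: ModelSpec, ds: Dataset) -> SampleWeights:
    if spec.sample_weighting == "uniform":
        return uniform_sample_weights(ds.n_samples)
    if spec.sample_weighting == "simple":
        return simple_sample_weights(ds.Y)
    d = 1 if spec.sample_weighting == "linear" else 2
    return distance_sample_weights(ds.y, ds.Y, ds.t, d=d)


def fit_predict(
    spec: ModelSpec,
    train: Dataset,
    X_test: np.ndarray,
    params: ForestParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the specified model on ``train`` and predict (class, value) for ``X_test``.

    Imbalance countermeasures are computed from the training samples only.
    """
    if spec.kind == "crf":
        forest = ClassificationForest.fit(train, params)
        return forest.predict_class(X_test), crf_predict_value(forest, X_test)
    if spec.kind == "hierarchical":
        model = HierarchicalForest.fit(train, params)
        return model.predict_class(X_test), model.predict_value(X_test)

    if spec.resampling == "upsample":
        train = upsample(train, seed=params.seed)
    elif spec.resampling == "proportional":
        train = proportional_upsample(train, seed=params.seed)
    weights = _make_weights(spec, train)
    scheme: TreeWeighting
    if spec.kind == "rrf":
        scheme = "uniform"
    elif spec.kind == "harf":
        scheme = "binary"
    else:
        scheme = spec.tree_weighting
    forest = fit_forest(
        train,
        weights,
        ForestParams(
            B=params.B,
            m=params.m,
            min_samples_leaf=params.min_samples_leaf,
            seed=params.seed,
            tree_weighting=scheme,
        ),
    )
    value = forest.predict_value(X_test)
    if spec.kind == "rrf":
        cls = rrf_classify(value, train.t)
    else:
        cls = forest.predict_class(X_test)
    return cls, value


@dataclass(frozen=True)
class GridPoint:
    """One hyperparameter combination of the CV grid."""

    n_features: int = 20
    B: int = 500
    m: int | None = None
    min_samples_leaf: int = 5

    def forest_params(self, seed: int, tree_weighting: TreeWeighting) -> ForestParams:
        return ForestParams(
            B=self.B,
            m=self.m,
            min_samples_leaf=self.min_samples_leaf,
            seed=seed,
            tree_weighting=tree_weighting,
        )


@dataclass
class CVConfig:
    """Train/test and cross-validation settings.

    Defaults follow the standard protocol: 20% held-out test set, 5-fold
    CV, and a grid over the number of mRMR-selected genes
    {20, 40, 60, 80, 100}.
    """

    test_fraction: float = 0.2
    n_folds: int = 5
    grid: list[GridPoint] = field(
        default_factory=lambda: [GridPoint(n_features=k) for k in (20, 40, 60, 80, 100)]
    )
    selection_metric: Literal["auto", "mcc", "mse"] = "auto"
    mrmr_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.grid:
            raise ValueError("grid must be non-empty")


@dataclass
class ExperimentResult:
    """Output of :func:`run_experiment`."""

    report: EvaluationReport
    chosen: GridPoint
    cv_scores: dict
    selected_genes: list[str]
    test_sample_ids: list[str]


def train_test_split_ids(ds: Dataset, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test split by random drawing without replacement (not stratified)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    n_test = int(round(test_fraction * ds.n_samples))
    n_test = min(max(n_test, 1), ds.n_samples - 1)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _select_and_fit(
    spec: ModelSpec,
    train: Dataset,
    X_eval: np.ndarray,
    point: GridPoint,
    mrmr_bins: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    k = min(point.n_features, train.n_genes)
    sel = greedy_mrmr(train.X, train.y, k=k, gene_ids=train.gene_ids, n_bins=mrmr_bins)
    cols = [train.gene_ids.index(g) for g in sel.selected]
    sub = train.select_genes(sel.selected)
    params = point.forest_params(seed=seed, tree_weighting=spec.tree_weighting)
    cls, val = fit_predict(spec, sub, X_eval[:, cols], params)
    return cls, val, sel.selected


def run_experiment(ds: Dataset, spec: ModelSpec, cv: CVConfig) -> ExperimentResult:
    """Full protocol: split, CV model selection, final refit, test report.

    Feature selection is refit inside every CV fold and again on the full
    training set before the final fit. Classifying models are selected by
    maximal mean validation MCC, pure-regression models (rRF) by minimal
    mean validation MSE. A grid point whose fold training data loses a
    class the model needs is marked failed and skipped.
    """
    metric = cv.selection_metric
    if metric == "auto":
        metric = "mcc" if spec.classifies_by_vote else "mse"

    train_idx, test_idx = train_test_split_ids(ds, cv.test_fraction, cv.seed)
    train, test = ds.subset(train_idx), ds.subset(test_idx)

    kf = KFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    cv_scores: dict[GridPoint, float] = {}
    for point in cv.grid:
        fold_scores = []
        failed = False
        for tr_i, va_i in kf.split(np.arange(train.n_samples)):
            ftrain, fval = train.subset(tr_i), train.subset(va_i)
            needs_both = spec.kind != "rrf" or spec.sample_weighting != "uniform" or spec.resampling != "none"
            if needs_both and len(np.unique(ftrain.Y)) < 2:
                failed = True
                break
            cls, val, _ = _select_and_fit(
                spec, ftrain, fval.X, point, cv.mrmr_bins, cv.seed
            )
            if metric == "mcc":
                fold_scores.append(classification_metrics(fval.Y, cls)["mcc"])
            else:
                fold_scores.append(float(np.mean((fval.y - val) ** 2)))
        if failed:
            logger.warning("grid point %s failed (single-class fold); skipped", point)
            continue
        cv_scores[point] = float(np.mean(fold_scores))
    if not cv_scores:
        raise RuntimeError("every grid point failed during cross-validation")

    if metric == "mcc":
        chosen = max(cv_scores, key=lambda p: (cv_scores[p], -cv.grid.index(p)))
    else:
        chosen = min(cv_scores, key=lambda p: (cv_scores[p], cv.grid.index(p)))

    cls, val, genes = _select_and_fit(spec, train, test.X, chosen, cv.mrmr_bins, cv.seed)
    report = evaluate_predictions(test.y, val, test.Y, cls)
    return ExperimentResult(
        report=report,
        chosen=chosen,
        cv_scores={repr(k): v for k, v in cv_scores.items()},
        selected_genes=genes,
        test_sample_ids=test.sample_ids,
    )
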