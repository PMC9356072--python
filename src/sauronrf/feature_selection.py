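"""Greedy minimum-redundancy-maximum-relevance (mRMR) gene selection.

Relevance and redundancy are measured by plug-in mutual information (in
nats) after independent equal-frequency (quantile) discretization of each
variable. Quantile binning is scale-free, which suits expression data whose
units are array-dependent. The greedy criterion is the difference form
(MID): pick the feature maximizing ``MI(f, y) - mean MI(f, selected)``; a
quotient form (MIQ) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BINS = 10


@dataclass(frozen=True)
class MrmrResult:
    """Ordered selection with per-gene relevance and redundancy at pick time."""

    selected: list[str]
    relevance: list[float]
    redundancy_at_selection: list[float]


def quantile_bin(a: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into (at most) ``n_bins`` equal-frequency bins.

    Duplicate quantile edges collapse, so low-cardinality input yields
    fewer bins; a constant vector yields a single bin.
    """
    a = np.asarray(a, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    edges = np.unique(np.quantile(a, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, a, side="left")


def _plugin_mi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Plug-in MI (nats) of two integer label vectors; log(0) terms skipped."""
    n = labels_a.size
    ka = int(labels_a.max()) + 1
    kb = int(labels_b.max()) + 1
    joint = np.bincount(labels_a * kb + labels_b, minlength=ka * kb).reshape(ka, kb)
    joint = joint / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Plug-in mutual information of two real vectors after quantile binning.

    Both variables are discretized independently into ``n_bins``
    equal-frequency bins; the result is in nats and nonnegative. A constant
    vector has a single bin, giving MI = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    if a.size < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} observations for {n_bins} bins")
    la, lb = quantile_bin(a, n_bins), quantile_bin(b, n_bins)
    # canonical argument order makes MI(a, b) == MI(b, a) bit-exact
    if la.tobytes() > lb.tobytes():
        la, lb = lb, la
    return _plugin_mi(la, lb)


def greedy_mrmr(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    gene_ids: list[str] | None = None,
    n_bins: int = DEFAULT_BINS,
    quotient: bool = False,
) -> MrmrResult:
    """Select ``k`` features by greedy mRMR against response ``y``.

    The first pick maximizes relevance ``MI(f, y)``; each later pick
    maximizes relevance minus the mean MI with the already-selected set
    (or the ratio, with ``quotient=True``). Argmax ties break on the
    lexicographically smallest gene ID, making the result deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if gene_ids is None:
        gene_ids = [f"f{j}" for j in range(p)]
    if len(gene_ids) != p:
        raise ValueError("gene_ids length must match X columns")
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")

    binned = np.column_stack([quantile_bin(X[:, j], n_bins) for j in range(p)])
    y_binned = quantile_bin(y, n_bins)
    relevance = np.array([_plugin_mi(binned[:, j], y_binned) for j in range(p)])

    # lexicographic gene-ID tie-break: argmax over (score, reversed-ID rank)
    id_rank = np.argsort(np.argsort(gene_ids))

    selected: list[int] = []
    sel_rel: list[float] = []
    sel_red: list[float] = []
    redundancy_sum = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for step in range(k):
        if step == 0:
            score = relevance.copy()
        else:
            mi_last = np.array(
                [
                    _plugin_mi(binned[:, j], binned[:, selected[-1]]) if remaining[j] else 0.0
                    for j in range(p)
                ]
            )
            redundancy_sum += mi_last
            mean_red = redundancy_sum / len(selected)
            if quotient:
                score = relevance / np.maximum(mean_red, 1e-12)
            else:
                score = relevance - mean_red
        score = np.where(remaining, score, -np.inf)
        best = score.max()
        cand = np.flatnonzero(score == best)
        j = cand[np.argmin(id_rank[cand])]
        selected.append(int(j))
        sel_rel.append(float(relevance[j]))
        sel_red.append(float(redundancy_sum[j] / step) if step > 0 else 0.0)
        remaining[j] = False

    return MrmrResult(
        selected=[gene_ids[j] for j in selected],
        relevance=sel_rel,
        redundancy_at_selection=sel_red,
    )
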