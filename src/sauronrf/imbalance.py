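"""Countermeasures against class imbalance at the sample level.

Two families: initial per-sample importance weights ``w*`` that are carried
through tree training (uniform / simple / linear / quadratic), and
row-duplication schemes that balance the classes before training (plain and
proportional upsampling). The simple weights give every sensitive sample
weight N_res/N_sens so the two classes carry equal total mass; the distance
weights emphasize samples far from the threshold t, normalized so each
class's weights sum to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .datasets import Dataset

Scheme = Literal["uniform", "simple", "linear", "quadratic"]


@dataclass(frozen=True)
class SampleWeights:
    """Initial per-sample importance weights ``w*`` with their scheme tag."""

    w_star: np.ndarray
    scheme: Scheme
    d: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.w_star, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("w_star must be a non-empty vector")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")
        object.__setattr__(self, "w_star", w)


def uniform_sample_weights(n: int) -> SampleWeights:
    """The no-countermeasure baseline: every sample has weight 1."""
    return SampleWeights(w_star=np.ones(n), scheme="uniform")


def _require_both_classes(Y: np.ndarray) -> tuple[int, int]:
    n_sens = int(Y.sum())
    n_res = int(Y.size - n_sens)
    if n_sens == 0 or n_res == 0:
        raise ValueError("both classes must be present")
    return n_sens, n_res


def simple_sample_weights(Y: np.ndarray) -> SampleWeights:
    """Weight 1 for resistant samples, N_res/N_sens for sensitive ones.

    Equalizes the total weight mass of the two classes (both sums equal
    N_res).
    """
    Y = np.asarray(Y, dtype=int)
    n_sens, n_res = _require_both_classes(Y)
    w = np.where(Y == 1, n_res / n_sens, 1.0)
    return SampleWeights(w_star=w, scheme="simple")


def distance_sample_weights(
    y: np.ndarray, Y: np.ndarray, t: float, d: int = 1
) -> SampleWeights:
    """Threshold-distance weights: ``w* = |y - t|^d / (2 * class sum)``.

    Each class's weights sum to 0.5 (total mass 1), and samples farther
    from the threshold dominate; ``d=1`` is the linear scheme, ``d=2``
    quadratic.
    """
    if d not in (1, 2):
        raise ValueError("d must be 1 or 2")
    y = np.asarray(y, dtype=float)
    Y = np.asarray(Y, dtype=int)
    _require_both_classes(Y)
    dist = np.abs(y - t) ** d
    w = np.empty_like(dist)
    for cls in (0, 1):
        mask = Y == cls
        denom = dist[mask].sum()
        if denom == 0:
            raise ValueError(
                f"all samples of class {cls} lie exactly at the threshold"
            )
        w[mask] = dist[mask] / (2.0 * denom)
    return SampleWeights(w_star=w, scheme="linear" if d == 1 else "quadratic", d=d)


def upsample(ds: Dataset, seed: int) -> Dataset:
    """Balance classes by drawing sensitive rows with replacement.

    Adds seeded random copies of sensitive samples until both classes have
    N_res rows; all original rows are retained and duplicates get suffixed
    IDs.
    """
    n_sens, n_res = _require_both_classes(ds.Y)
    if n_sens > n_res:
        raise ValueError("sensitive class must be the minority")
    sens_idx = np.flatnonzero(ds.Y == 1)
    rng = np.random.default_rng(seed)
    extra = rng.choice(sens_idx, size=n_res - n_sens, replace=True)
    idx = np.concatenate([np.arange(ds.n_samples), extra])
    return ds.subset(idx, suffix_duplicates=True)


def proportional_upsample(ds: Dataset, seed: int = 0) -> Dataset:
    """Balance classes with copy counts proportional to threshold distance.

    Linear distance weights of the sensitive samples (doubled so they sum
    to 1) give each sample an importance share; its target row count is
    that share times N_res, rounded half-to-even with a largest-remainder
    repair so the sensitive class ends at exactly N_res rows. The ``seed``
    is accepted for interface symmetry; the procedure is deterministic.
    """
    n_sens, n_res = _require_both_classes(ds.Y)
    if n_sens > n_res:
        raise ValueError("sensitive class must be the minority")
    sens_idx = np.flatnonzero(ds.Y == 1)
    dist = np.abs(ds.y[sens_idx] - ds.t)
    total = dist.sum()
    if total == 0:
        raise ValueError("all sensitive samples lie exactly at the threshold")
    importance = dist / total  # linear weights x 2: sums to 1 over sensitives
    targets = importance * n_res
    counts = np.rint(targets).astype(int)  # numpy rint rounds half to even
    # largest-remainder repair so sensitive rows total exactly N_res
    while counts.sum() != n_res:
        residual = targets - counts
        if counts.sum() < n_res:
            counts[np.argmax(residual)] += 1
        else:
            counts[np.argmin(residual)] -= 1
    res_idx = np.flatnonzero(ds.Y == 0)
    idx = np.concatenate([res_idx, np.repeat(sens_idx, counts)])
    idx.sort(kind="stable")
    return ds.subset(idx, suffix_duplicates=True)
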