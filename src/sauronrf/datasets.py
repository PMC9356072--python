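"""Domain types and I/O: expression matrices, drug-response tables, binarization.

A :class:`Dataset` bundles everything one drug's prediction problem needs:
an expression matrix ``X`` (samples x genes), the continuous response ``y``
(logarithmized IC50), its binarized counterpart ``Y`` (1 = sensitive,
0 = resistant) and the drug-specific threshold ``t`` that links the two.
Lower IC50 means greater sensitivity, so a sample is sensitive iff
``y < t``; samples exactly at the threshold count as resistant (the
conservative clinical default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Orientation = Literal["samples_by_genes", "genes_by_samples"]


@dataclass(frozen=True)
class ClassCounts:
    """Number of sensitive (minority) and resistant (majority) samples."""

    n_sens: int
    n_res: int

    @property
    def total(self) -> int:
        return self.n_sens + self.n_res

    @property
    def ratio(self) -> float:
        """Imbalance ratio N_res / N_sens; the simple sample weight of the minority."""
        if self.n_sens == 0:
            raise ValueError("ratio undefined: no sensitive samples")
        return self.n_res / self.n_sens


@dataclass
class Dataset:
    """Aligned expression/response data for a single drug.

    Rows of ``X``, entries of ``y`` and ``Y`` are all indexed by
    ``sample_ids`` in order. ``Y`` must be consistent with ``y`` and ``t``
    under the binarization rule ``Y[i] = 1 iff y[i] < t``.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    Y: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.Y = np.asarray(self.Y, dtype=int)
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.y) != n or len(self.Y) != n:
            raise ValueError("sample_ids, X rows, y and Y must have equal length")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length must match X columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene_ids")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y must be binary (0/1)")
        if not np.array_equal(self.Y, binarize(self.y, self.t)):
            raise ValueError("Y inconsistent with binarize(y, t)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> ClassCounts:
        n_sens = int(self.Y.sum())
        return ClassCounts(n_sens=n_sens, n_res=self.n_samples - n_sens)

    def subset(self, idx: np.ndarray, suffix_duplicates: bool = False) -> "Dataset":
        """Row-subset (or re-sample) the dataset by integer indices.

        With ``suffix_duplicates``, repeated rows get ``#k`` ID suffixes so
        sample IDs stay unique — used by the upsampling schemes.
        """
        idx = np.asarray(idx, dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        if suffix_duplicates:
            seen: dict[str, int] = {}
            out = []
            for s in ids:
                k = seen.get(s, 0)
                seen[s] = k + 1
                out.append(s if k == 0 else f"{s}#{k}")
            ids = out
        return Dataset(
            sample_ids=ids,
            gene_ids=list(self.gene_ids),
            X=self.X[idx],
            y=self.y[idx],
            Y=self.Y[idx],
            t=self.t,
        )

    def select_genes(self, gene_ids: list[str]) -> "Dataset":
        """Column-subset to the given genes, in the given order."""
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"unknown gene IDs: {missing}")
        cols = [pos[g] for g in gene_ids]
        return replace(self, gene_ids=list(gene_ids), X=self.X[:, cols])


def binarize(y: np.ndarray, t: float) -> np.ndarray:
    """Binarize a continuous response against a drug-specific threshold.

    ``Y[i] = 1`` (sensitive) iff ``y[i] < t``, else 0 (resistant). Values
    exactly at the threshold are resistant.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(t):
        raise ValueError("threshold t must be finite")
    if not np.all(np.isfinite(y)):
        bad = np.flatnonzero(~np.isfinite(y))
        raise ValueError(f"non-finite response values at positions {bad.tolist()}")
    return (y < t).astype(int)


def load_expression(path: str | Path, orientation: Orientation = "samples_by_genes") -> pd.DataFrame:
    """Read a delimited expression matrix into a samples x genes DataFrame.

    The file must have one header row and one leading ID column; the
    delimiter (tab or comma) is sniffed. With ``orientation=
    'genes_by_samples'`` the matrix is transposed after reading.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation: {orientation!r}")
    _check_unique(df.index, "sample")
    _check_unique(df.columns, "gene")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"non-numeric value in column {col!r} at row(s) {list(bad[:5])}"
            )
        df[col] = coerced
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)]
        raise ValueError(f"missing values in expression matrix at row(s) {list(rows[:5])}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def load_response(path: str | Path) -> dict[str, float]:
    """Read a two-column (sample_id, ln_ic50) response table."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("response table needs at least two columns (sample_id, value)")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(ids, "sample")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        bad = ids[vals.isna()]
        raise ValueError(f"non-numeric response for sample(s) {list(bad[:5])}")
    return dict(zip(ids, vals.astype(float)))


def load_threshold_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (drug_id, threshold) table of binarization thresholds."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("threshold table needs two columns (drug_id, threshold)")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(ids, "drug")
    vals = pd.to_numeric(df.iloc[:, 1], errors="raise")
    return dict(zip(ids, vals.astype(float)))


def align(expr: pd.DataFrame, response: Mapping[str, float], t: float) -> Dataset:
    """Intersect expression and response on sample IDs and build a Dataset.

    Only samples with complete information (present in both inputs) are
    kept; dropped counts are logged. Output rows are in lexicographic
    sample-ID order so downstream randomness is governed by seeds alone.
    """
    if expr.shape[0] == 0 or len(response) == 0:
        raise ValueError("empty input")
    expr_ids = set(map(str, expr.index))
    resp_ids = set(map(str, response.keys()))
    common = sorted(expr_ids & resp_ids)
    if not common:
        raise ValueError("no samples shared between expression and response")
    dropped = (len(expr_ids) - len(common)) + (len(resp_ids) - len(common))
    if dropped:
        logger.info("align: dropped %d samples without complete information", dropped)
    X = expr.loc[common].to_numpy(dtype=float)
    y = np.array([response[s] for s in common], dtype=float)
    return Dataset(
        sample_ids=common,
        gene_ids=[str(g) for g in expr.columns],
        X=X,
        y=y,
        Y=binarize(y, t),
        t=float(t),
    )


def _check_unique(index, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} IDs: {dups}")
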