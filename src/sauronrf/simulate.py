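"""Synthetic GDSC-like expression/response data with controllable imbalance.

The generator emulates the structure of a cancer cell-line drug screen: a
few hundred samples, high-dimensional log-scale expression, and a
continuous ln(IC50) response whose distribution is a mixture of a minority
"sensitive" mode and a majority "resistant" mode (default 9% sensitive,
i.e. the typical ~1:10 ratio). A latent Bernoulli class drives both a
mean-shift in the informative genes and the response mode, so the method's
premise — distinct average responses per class, predictable from
expression — holds by construction and is tunable.

Concretely, with latent class z_i ~ Bernoulli(frac_sensitive):

* informative genes: N(-class_shift * z_i, 1); other genes N(0, 1);
* response: y_i = ±effect_size/2 (sensitive mode lower) plus a
  class-centered linear combination of the informative genes plus
  N(0, noise_sd) — class-centering keeps the mode separation exactly
  ``effect_size``;
* threshold t = midpoint of the two modes, so binarization recovers the
  latent class with an error rate set by the within-mode spread.

Not emulated: gene-gene correlation beyond the shared class signal, batch
effects, or real GDSC marginals — conclusions from this generator speak to
the imbalance mechanics, not to absolute performance on real screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Dataset, binarize

GENERATOR_VERSION = 1


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror a single-drug GDSC-scale problem."""

    n_samples: int = 800
    n_genes: int = 300
    n_informative: int = 20
    frac_sensitive: float = 0.09
    effect_size: float = 3.0
    noise_sd: float = 1.0
    class_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 samples and 1 gene")
        if not 0 < self.n_informative <= self.n_genes:
            raise ValueError("n_informative must be in [1, n_genes]")
        if not 0 < self.frac_sensitive < 0.5:
            raise ValueError("frac_sensitive must be in (0, 0.5)")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be nonnegative")


def generate(cfg: SimConfig, return_truth: bool = False):
    """Draw one synthetic dataset; optionally also the ground truth.

    With ``return_truth=True`` returns ``(dataset, truth)`` where ``truth``
    holds the latent class vector and the informative gene IDs, for oracle
    tests; otherwise just the :class:`Dataset`.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p, k = cfg.n_samples, cfg.n_genes, cfg.n_informative
    z = (rng.random(n) < cfg.frac_sensitive).astype(int)
    X = rng.standard_normal((n, p))
    # sensitive samples' informative genes are shifted down, like expression
    # loss driving sensitivity
    X[:, :k] -= cfg.class_shift * z[:, None]
    beta = np.full(k, 1.0 / np.sqrt(k))
    contrib = X[:, :k] @ beta
    # class-center the gene contribution so the response modes are separated
    # by exactly effect_size
    contrib -= np.where(z == 1, -cfg.class_shift * beta.sum(), 0.0)
    base = np.where(z == 1, -cfg.effect_size / 2.0, cfg.effect_size / 2.0)
    y = base + contrib + rng.normal(0.0, cfg.noise_sd, size=n)
    t = 0.0  # midpoint of the two response modes
    gene_ids = [f"g{j:04d}" for j in range(p)]
    ds = Dataset(
        sample_ids=[f"CL{i:04d}" for i in range(n)],
        gene_ids=gene_ids,
        X=X,
        y=y,
        Y=binarize(y, t),
        t=t,
    )
    if not return_truth:
        return ds
    truth = {
        "latent_class": z,
        "informative_genes": gene_ids[:k],
        "generator_version": GENERATOR_VERSION,
    }
    return ds, truth


def toy_fixture() -> Dataset:
    """Tiny hand-specified dataset (N=10, P=3) for brute-force oracle tests.

    Values are fixed constants with both classes present and generic
    (tie-free) expression values; repeated calls are identical.
    """
    sample_ids = [f"s{i}" for i in range(10)]
    gene_ids = ["gA", "gB", "gC"]
    X = np.array(
        [
            [0.31, -1.27, 0.58],
            [1.94, 0.41, -0.73],
            [-0.62, 2.13, 1.17],
            [0.08, -0.55, -1.91],
            [2.47, 1.02, 0.29],
            [-1.13, 0.77, -0.44],
            [0.89, -2.01, 1.63],
            [1.52, 0.18, -0.09],
            [-0.27, 1.44, 0.96],
            [0.66, -0.88, -1.35],
        ]
    )
    y = np.array([-3.1, 1.4, -2.6, 0.9, 2.2, -1.8, 1.1, 2.8, -0.7, 0.5])
    t = -0.25
    return Dataset(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        X=X,
        y=y,
        Y=binarize(y, t),
        t=t,
    )
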