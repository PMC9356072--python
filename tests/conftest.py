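import numpy as np
import pytest

from sauronrf import SimConfig, generate, toy_fixture


@pytest.fixture
def toy():
    """Tiny hand-specified dataset (N=10, P=3) with both classes present."""
    return toy_fixture()


@pytest.fixture(scope="session")
def small_imbalanced():
    """A modest imbalanced synthetic dataset for workflow-level tests."""
    return generate(
        SimConfig(n_samples=150, n_genes=25, n_informative=5, frac_sensitive=0.15, seed=7)
    )


def single_leaf_tree(value, cls, mass0, mass1, count0=None, count1=None):
    """Hand-built one-node tree for aggregation-rule oracle tests."""
    from sauronrf import AnnotatedTree

    if count0 is None:
        count0 = int(round(mass0))
    if count1 is None:
        count1 = int(round(mass1))
    return AnnotatedTree(
        children_left=np.array([-1]),
        children_right=np.array([-1]),
        feature=np.array([-2]),
        threshold=np.array([-2.0]),
        leaf_value=np.array([float(value)]),
        leaf_class=np.array([int(cls)]),
        mass0=np.array([float(mass0)]),
        mass1=np.array([float(mass1)]),
        count0=np.array([count0]),
        count1=np.array([count1]),
        bootstrap_idx=np.array([0]),
        importances=np.zeros(1),
    )
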