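import numpy as np
import pytest

from pathrobust.data import LabelledExpression, PathwayCollection
from pathrobust.synthetic import SyntheticParams, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expression(n=12, m=10, n_classes=2, seed=0, groups=False):
    """Small random expression fixture with balanced classes."""
    r = np.random.default_rng(seed)
    values = r.standard_normal((n, m))
    classes = np.array([f"c{i % n_classes}" for i in range(n)], dtype=object)
    group_labels = None
    if groups:
        group_labels = np.array(
            [f"g{(i % n_classes)}_{(i // n_classes) % 3}" for i in range(n)],
            dtype=object)
    return LabelledExpression(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(m)],
        class_labels=classes,
        group_labels=group_labels,
    )


@pytest.fixture
def tiny_expr():
    return make_expression(n=12, m=10)


@pytest.fixture
def tiny_coll():
    return PathwayCollection(pathways={
        "P1": frozenset({"g0", "g1", "g2"}),
        "P2": frozenset({"g2", "g3", "g4", "g5"}),
        "P3": frozenset({"g6", "g7"}),
    }, source_db={"P1": "dbA", "P2": "dbA", "P3": "dbB"})


@pytest.fixture(scope="session")
def small_synthetic():
    """Small but fully structured synthetic dataset for pipeline tests."""
    params = SyntheticParams(n_samples=60, n_classes=3, groups_per_class=4,
                             n_genes=400, n_pathways=20, q_min=8, q_max=15,
                             n_informative=6, seed=7)
    return generate_synthetic(params)


@pytest.fixture(scope="session")
def study_synthetic():
    """Synthetic dataset at the default study conditions."""
    return generate_synthetic(SyntheticParams(seed=0))
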