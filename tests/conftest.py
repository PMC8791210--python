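import numpy as np
import pytest

import sparsecca as sc
from sparsecca.data_io import StandardizedPair, zscore


@pytest.fixture(scope="session")
def strong_pair():
    """Default-strength planted mode at study shapes (53 x 59 / 53 x 86)."""
    spec = sc.SyntheticSpec(seed=7)
    bx, by, truth = sc.generate_paired_data(spec)
    return sc.standardize_pair(bx, by), truth


@pytest.fixture(scope="session")
def null_pair():
    """Independent Gaussian blocks at the same shapes."""
    bx, by = sc.generate_null_data(53, 59, 86, seed=11)
    return sc.standardize_pair(bx, by)


def random_pair(n, p, q, seed):
    """Standardized pair of independent Gaussian blocks (no FeatureTable)."""
    rng = np.random.default_rng(seed)
    return StandardizedPair(
        X=zscore(rng.standard_normal((n, p))),
        Y=zscore(rng.standard_normal((n, q))),
        names_x=[f"x{j}" for j in range(p)],
        names_y=[f"y{j}" for j in range(q)],
        subject_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def table_factory():
    def make(values, ids=None, names=None, **kw):
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        ids = ids or [f"s{i + 1}" for i in range(n)]
        names = names or [f"v{j + 1}" for j in range(p)]
        return sc.FeatureTable(ids, names, values, **kw)

    return make
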