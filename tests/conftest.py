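import numpy as np
import pandas as pd
import pytest

from depth2 import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_expr():
    """3 genes x 3 samples, linear scale."""
    data = pd.DataFrame(
        {"S1": [0.0, 2.0, 5.0], "S2": [1.0, 1.0, 5.0], "S3": [2.0, 0.0, 6.0]},
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data, scale="linear")


def random_matrix(rng, m, t, scale=2.0):
    """Random log-scale matrix with heterogeneous per-gene spread."""
    base = rng.uniform(2, 12, size=(m, 1))
    sds = rng.uniform(0.1, scale, size=(m, 1))
    vals = base + rng.normal(0, 1, size=(m, t)) * sds
    genes = [f"g{i}" for i in range(m)]
    samples = [f"s{j}" for j in range(t)]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=samples), scale="log2p1"
    )
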