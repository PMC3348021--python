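import numpy as np
import pytest

from pdnsbic import ExpressionMatrix


def make_matrix(values, gene_prefix="g", cond_prefix="c") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        values,
        tuple(f"{gene_prefix}{i}" for i in range(n)),
        tuple(f"{cond_prefix}{j}" for j in range(m)),
    )


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 conditions with one increasing, one decreasing, one flat row."""
    return make_matrix(
        [
            [1.0, 2.0, 3.0, 4.0],
            [8.0, 6.0, 4.0, 2.0],
            [5.0, 5.0, 5.0, 5.0],
        ]
    )


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(size=(12, 6)))
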