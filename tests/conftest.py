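import numpy as np
import pytest

from csnet import ExpressionMatrix


@pytest.fixture
def tiny_gem():
    """3 genes x 4 cells with zeros and ties."""
    values = np.array(
        [
            [1.0, 0.0, 2.0, 2.0],
            [3.0, 1.0, 0.0, 4.0],
            [0.0, 0.0, 0.0, 5.0],
        ]
    )
    return ExpressionMatrix(values, ["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
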