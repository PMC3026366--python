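import numpy as np
import pytest

from tlgrn.preprocess import BinaryExpressionMatrix


@pytest.fixture
def fig_pair():
    """Two genes realizing the worked lag configuration.

    Gene A: OFF→ON at t=2, next change at t=6 (so initial change I_a = 2).
    Gene B: OFF→ON at t=3, no further change (I_b = 3).
    """
    a = [0, 1, 1, 1, 1, 0, 0, 0]
    b = [0, 0, 1, 1, 1, 1, 1, 1]
    return a, b


@pytest.fixture
def fig_pair_matrix(fig_pair):
    a, b = fig_pair
    return BinaryExpressionMatrix(["A", "B"], np.array([a, b]))


def random_binary(rng, length):
    return rng.integers(0, 2, size=length).tolist()
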