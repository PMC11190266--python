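import numpy as np
import pytest

from evhdesign import PottsModel, planted_model


@pytest.fixture
def tiny_model():
    """Planted chain model, L=6 / q=3, enumerable (729 states)."""
    return planted_model(6, 3, n_edges=3, coupling_strength=0.7, field_scale=0.5,
                         seed=1, topology="chain").model


@pytest.fixture
def dense_model():
    """Dense random symmetric model, L=5 / q=4, for exactness checks."""
    rng = np.random.default_rng(42)
    L, q = 5, 4
    h = rng.normal(size=(L, q))
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            block = rng.normal(size=(q, q))
            J[i, j] = block
            J[j, i] = block.T
    return PottsModel(h=h, J=J, alphabet="ACDE")


@pytest.fixture
def zero_model():
    L, q = 4, 3
    return PottsModel(h=np.zeros((L, q)), J=np.zeros((L, L, q, q)), alphabet="ACD")
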