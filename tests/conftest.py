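import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(potential, positions, h=1e-6):
    """Central-difference gradient of a scalar potential of node positions."""
    positions = np.asarray(positions, dtype=float)
    grad = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for j in range(3):
            up = positions.copy()
            up[i, j] += h
            dn = positions.copy()
            dn[i, j] -= h
            grad[i, j] = (potential(up) - potential(dn)) / (2.0 * h)
    return grad
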