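import itertools

import numpy as np
import pytest

from ppv23_cea.parameters import load_parameters


@pytest.fixture(scope="session")
def base_params():
    """Packaged base-case parameter set (shared, treated as immutable)."""
    return load_parameters()


def enumerate_cohort(probs: np.ndarray, n0: float, cycles: int) -> np.ndarray:
    """Brute-force oracle: occupancy by explicit enumeration of all state paths.

    Sums n0 x prod(P[path]) over every state sequence, so it shares nothing
    with the matrix-product implementation. O(k^cycles); fine for cycles <= 5.
    """
    k = probs.shape[0]
    occ = np.zeros((cycles + 1, k))
    occ[0, 0] = n0
    for c in range(1, cycles + 1):
        for path in itertools.product(range(k), repeat=c):
            mass = n0
            prev = 0
            for state in path:
                mass *= probs[prev, state]
                if mass == 0.0:
                    break
                prev = state
            occ[c, path[-1]] += mass
    return occ


def random_stochastic_matrix(seed: int) -> np.ndarray:
    """A random 5x5 row-stochastic matrix with absorbing death rows."""
    rng = np.random.default_rng(seed)
    m = rng.random((5, 5))
    m /= m.sum(axis=1, keepdims=True)
    m[3] = np.eye(5)[3]
    m[4] = np.eye(5)[4]
    return m
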