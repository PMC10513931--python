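import numpy as np
import pytest

from footprintflow.synthetic_data import WorldSpec, generate_world, planted_truth_world


def neumann_footprint(F, A, d, terms=300):
    """Independent truncated-series oracle for F @ (I-A)^-1 @ d.

    Sums F @ A^k @ d for k = 0..terms without any matrix inversion.
    """
    F = np.asarray(F, float)
    A = np.asarray(A, float)
    v = np.asarray(d, float).copy()
    total = F @ v
    for _ in range(terms):
        v = A @ v
        total = total + F @ v
    return total


@pytest.fixture(scope="session")
def small_world():
    """A 3-region x 6-sector synthetic world used across tests."""
    return generate_world(WorldSpec(n_regions=3, n_sectors=6, seed=42))


@pytest.fixture(scope="session")
def planted():
    return planted_truth_world(seed=11)
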