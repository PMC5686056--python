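"""Shared fixtures: phantoms and factorizations reused across test modules."""

import numpy as np
import pytest

from dcehabitat.decomposition import CurveMatrix, build_curve_matrix, decompose
from dcehabitat.io_core import TimeGrid
from dcehabitat.phantom import default_config, make_phantom


@pytest.fixture(scope="session")
def grid():
    return TimeGrid.default()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default one-lesion phantom without noise (series, truth)."""
    return make_phantom(default_config(snr=None, seed=0))


@pytest.fixture(scope="session")
def snr20_phantom():
    """Default one-lesion phantom at SNR 20 (series, truth)."""
    return make_phantom(default_config(snr=20, seed=0))


@pytest.fixture(scope="session")
def nmf_noiseless(noiseless_phantom):
    series, truth = noiseless_phantom
    return decompose(series, truth.masks["prostate"], k=3)


@pytest.fixture(scope="session")
def nmf_snr20(snr20_phantom):
    series, truth = snr20_phantom
    return decompose(series, truth.masks["prostate"], k=3)


@pytest.fixture(scope="session")
def exact_factorization(grid):
    """A curve matrix that is exactly W0 x S0 for three disjoint voxel groups.

    Returns (cm, W0, S0): 300 voxels in three blocks of 100, each block
    loading a single distinct non-negative temporal pattern.
    """
    # transient signatures with disjoint active windows: the factorization
    # of such a matrix is unique (up to permutation/scale), so exact
    # recovery is well-posed
    S0 = np.zeros((3, 12))
    S0[0, 2:5] = [0.6, 1.0, 0.4]  # early transient
    S0[1, 5:8] = [0.5, 1.0, 0.7]  # mid transient
    S0[2, 8:12] = [0.4, 0.8, 1.0, 0.9]  # late enhancement
    rng = np.random.default_rng(42)
    W0 = np.zeros((300, 3))
    for b in range(3):
        W0[b * 100 : (b + 1) * 100, b] = rng.uniform(50.0, 150.0, size=100)
    D = W0 @ S0
    shape = (10, 10, 3)
    coords = np.argwhere(np.ones(shape, dtype=bool))
    cm = CurveMatrix(D=D, coords=coords, shape=shape, grid=grid)
    return cm, W0, S0
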