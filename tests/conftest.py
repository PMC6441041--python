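import numpy as np
import pytest

from hornspike.maps import DensityMap, SoftMask


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def random_map(rng):
    return DensityMap(rng.normal(size=(16, 14, 12)), voxel_size=1.35,
                      origin=np.array([1.0, -2.0, 3.0]))


@pytest.fixture()
def gaussian_blob():
    """A smooth spherical blob fully inside a 32³ box (2 Å voxels)."""
    n = 32
    ax = (np.arange(n) - (n - 1) / 2) * 2.0
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return DensityMap(np.exp(-0.5 * d2 / 8.0**2), voxel_size=2.0)


def brute_force_local_correlation(map_grid, motif, mask):
    """Direct-sum masked Pearson at every fully-inside offset.

    Independent oracle for the FFT implementation: plain nested python/numpy
    sums straight from the definition.
    """
    M = np.asarray(map_grid, float)
    m = np.asarray(motif, float)
    w = np.asarray(mask, float)
    W = w.sum()
    mu = (w * m).sum() / W
    k = w * (m - mu)
    Vm = (w * (m - mu) ** 2).sum()
    out_shape = tuple(M.shape[a] - m.shape[a] + 1 for a in range(3))
    out = np.zeros(out_shape)
    for i in range(out_shape[0]):
        for j in range(out_shape[1]):
            for l in range(out_shape[2]):
                P = M[i:i + m.shape[0], j:j + m.shape[1], l:l + m.shape[2]]
                S1 = (w * P).sum()
                S2 = (w * P * P).sum()
                varM = S2 - S1 * S1 / W
                if varM <= 0 or Vm <= 0:
                    out[i, j, l] = 0.0
                else:
                    out[i, j, l] = (k * P).sum() / np.sqrt(varM * Vm)
    return out
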