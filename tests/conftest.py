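import numpy as np
import pytest

import neodose as nd
from neodose.phantoms import TISSUE_ORDER, VoxelModel


@pytest.fixture(scope="session")
def adult_table():
    return nd.load_adult_table()


@pytest.fixture(scope="session")
def scaled_table(adult_table):
    return nd.apply_age_scaling(adult_table, nd.load_neonate_scaling())


@pytest.fixture(scope="session")
def neonate_model():
    return nd.generate_phantom(nd.default_neonate_spec(seed=7))


@pytest.fixture(scope="session")
def sphere_model():
    return nd.generate_phantom(nd.sphere_spec(radius_mm=50.0, voxel_size_mm=2.0))


def toy_model(labels, voxel_size_mm=2.0, densities=None, names=None):
    """Hand-built VoxelModel for oracle tests (no generator involved)."""
    labels = np.asarray(labels, dtype=np.int16)
    present = sorted(set(labels.ravel()) - {0})
    names = names or {lab: TISSUE_ORDER[(lab - 1) % len(TISSUE_ORDER)]
                      for lab in present}
    densities = densities or {lab: 1000.0 for lab in present}
    m = VoxelModel(
        labels=labels,
        voxel_size=(voxel_size_mm,) * 3,
        tissue_names={int(k): v for k, v in names.items()},
        density={int(k): float(v) for k, v in densities.items()},
    )
    m.recompute_basic_masks()
    return m


def brute_force_ps10(sar, mass, target_kg):
    """Exhaustive reference for the 10 g peak: at every tissue center try
    every cube size with the fractional outer shell, entirely independent
    of the summed-area-table implementation."""
    shape = sar.shape
    power = sar * mass
    best = -np.inf
    best_loc = None
    valid = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if mass[i, j, k] <= 0:
                    continue
                m_prev = p_prev = 0.0
                n = 0
                while True:
                    if (i - n < 0 or j - n < 0 or k - n < 0
                            or i + n >= shape[0] or j + n >= shape[1]
                            or k + n >= shape[2]):
                        break  # cube left the grid before reaching the mass
                    sl = (slice(i - n, i + n + 1), slice(j - n, j + n + 1),
                          slice(k - n, k + n + 1))
                    m = float(mass[sl].sum())
                    p = float(power[sl].sum())
                    if m >= target_kg:
                        f = (target_kg - m_prev) / (m - m_prev)
                        val = (p_prev + f * (p - p_prev)) / target_kg
                        valid[i, j, k] = True
                        if val > best:
                            best = val
                            best_loc = (i, j, k)
                        break
                    m_prev, p_prev = m, p
                    n += 1
    return best, best_loc, valid
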