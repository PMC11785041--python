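import numpy as np
import pytest

from sfxm import ElementalMap, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_map(rng):
    """8x8 strictly positive map with anisotropic pixel steps."""
    values = rng.uniform(1.0, 50.0, size=(8, 8))
    return ElementalMap(values, dx=2.0, dy=1.0, element="Ca")


@pytest.fixture
def synthetic_map():
    """Deterministic 128x128 power-law map with plenty of counts."""
    return generate(SyntheticSpec(nx=128, ny=128, a_true=-3.5,
                                  mean_counts=500.0, seed=7)).map


def brute_force_dft2(psi):
    """Independent O(N^4) double-loop 2D DFT (unnormalized forward)."""
    ny, nx = psi.shape
    out = np.zeros((ny, nx), dtype=complex)
    for ky in range(ny):
        for kx in range(nx):
            acc = 0.0 + 0.0j
            for iy in range(ny):
                for ix in range(nx):
                    acc += psi[iy, ix] * np.exp(
                        -2j * np.pi * (ky * iy / ny + kx * ix / nx))
            out[ky, kx] = acc
    return out
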