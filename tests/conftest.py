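"""Shared fixtures: small Monte Carlo kernels and synthetic detection tiles.

Kernels are session-scoped because generation dominates test runtime; every
test that mutates a kernel must copy it first.
"""

import numpy as np
import pytest

import spheredose as sd
from spheredose.grid import make_grid
from spheredose.phantom import render_microct, single_sphere_integral
from spheredose.spheres import SphereTable

MICROCT_SPACING = 0.00874


@pytest.fixture(scope="session")
def kernel_36um():
    """36 μm kernel truncated at 0.72 mm (41³) — fast, for convolution tests."""
    return sd.generate_dpk(n_histories=10 ** 5, spacing_mm=0.036,
                           max_radius_mm=0.72, seed=101)


@pytest.fixture(scope="session")
def kernel_150um():
    """150 μm kernel at the automatic 99.9%-capture radius (full range)."""
    return sd.generate_dpk(n_histories=2 * 10 ** 5, spacing_mm=0.15, seed=102)


@pytest.fixture(scope="session")
def kernel_150um_short():
    """150 μm kernel truncated at 1.5 mm, for MIRD-limit style tests."""
    return sd.generate_dpk(n_histories=10 ** 5, spacing_mm=0.15,
                           max_radius_mm=1.5, seed=103)


def make_tile(positions_mm, shape=(128, 128, 128), noise_sd=15.0, seed=0,
              spacing=MICROCT_SPACING):
    grid = make_grid(shape, spacing)
    table = SphereTable(np.asarray(positions_mm), np.zeros(len(positions_mm)))
    return render_microct(table, grid, noise_sd=noise_sd, seed=seed)


@pytest.fixture(scope="session")
def default_tile():
    """The default synthetic detection tile: 128³ voxels at 8.74 μm with 200
    spheres at uniform random positions (SNR well above 10)."""
    rng = np.random.default_rng(42)
    extent = 128 * MICROCT_SPACING
    pos = rng.uniform(0.03, extent - 0.03, (200, 3))
    return make_tile(pos, seed=43), pos


@pytest.fixture(scope="session")
def single_sphere_ref():
    return single_sphere_integral(MICROCT_SPACING)
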