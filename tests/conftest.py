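"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest

from pomecell.phantom import apple_config, generate_phantom, pear_config


@pytest.fixture(scope="session")
def apple_phantom():
    """Noise-free apple-style phantom, 48^3 voxels."""
    return generate_phantom(apple_config(seed=11, shape=(48, 48, 48), noise_sd=0.0))


@pytest.fixture(scope="session")
def pear_phantom():
    """Noise-free pear-style phantom with a stone cluster, 48^3 voxels."""
    return generate_phantom(
        pear_config(seed=12, shape=(48, 48, 48), noise_sd=0.0,
                    stone_cell_density=2.0))


@pytest.fixture(scope="session")
def noisy_apple_phantom():
    """Apple phantom at the default noise level."""
    return generate_phantom(apple_config(seed=13, shape=(48, 48, 48)))


def digitized_ball(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    z, y, x = np.mgrid[:n, :n, :n]
    c = n // 2
    return ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= radius * radius
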