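from __future__ import annotations

import numpy as np
import pytest

from wmhseg import BinaryMask, Grid, generate_phantom
from wmhseg.phantom import default_phantom_spec


def make_grid(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)) -> Grid:
    return Grid(tuple(shape), np.diag(list(spacing) + [1.0]))


def random_mask(rng: np.random.Generator, shape=(16, 16, 16), p=0.3) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p, make_grid(shape))


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Deterministic phantom with zero noise: WM mode 100, lesions at 180."""
    spec = default_phantom_spec(seed=1, noise_sd=0.0)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Well-defined lesions (1.8x WM) under 10% additive noise."""
    spec = default_phantom_spec(seed=2, noise_sd=10.0)
    return spec, generate_phantom(spec)
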