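import numpy as np
import pytest

import skincap as sc


@pytest.fixture(scope="session")
def default_study() -> sc.SyntheticStudy:
    """One paper-like synthetic study, shared across tests (seed 1)."""
    return sc.generate_study(sc.default_design(1))


@pytest.fixture(scope="session")
def default_roi() -> sc.RoiRect:
    return sc.RoiRect(118, 96, 64, 64)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_grid(rng: np.random.Generator, shape, low=0, high=256) -> np.ndarray:
    return rng.integers(low, high, size=shape).astype(np.uint8)
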