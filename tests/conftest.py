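from __future__ import annotations

import numpy as np
import pytest

from landmarkerr import (
    LandmarkConfiguration,
    LandmarkDataset,
    default_schemes,
    make_template,
)


@pytest.fixture(scope="session")
def toad_schemes():
    return default_schemes()


@pytest.fixture(scope="session")
def toad_template():
    return make_template("toad_like")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigidly_move(coords: np.ndarray, rng: np.random.Generator, scale_range=(1.0, 1.0)) -> np.ndarray:
    """Random rigid motion (plus optional scale) of one configuration."""
    r = random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    s = rng.uniform(*scale_range)
    return s * (coords @ r.T) + t


def dataset_from_blocks(blocks, scheme, distance_scheme=None) -> LandmarkDataset:
    """Build a dataset from (individual, method, replicate, coords) tuples."""
    configs = [
        LandmarkConfiguration(ind, method, rep, coords) for ind, method, rep, coords in blocks
    ]
    return LandmarkDataset(configs, scheme, distance_scheme)
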