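"""Shared fixtures: small spectra, tables, and one cached default scene."""

from __future__ import annotations

import numpy as np
import pytest

from msistrat import (
    FeatureTable,
    PixelSpectrum,
    VoidMask,
    generate,
    make_default_scene,
)
from msistrat.datatypes import SEDIMENT, VOID


@pytest.fixture
def simple_spectrum() -> PixelSpectrum:
    return PixelSpectrum(
        0,
        0,
        np.array([200.0, 350.5, 500.25, 780.1]),
        np.array([2.0, 4.0, 6.0, 8.0]),
        np.array([3.9, 4.0, 10.0, 25.0]),
    )


@pytest.fixture
def small_table() -> FeatureTable:
    """4 pixels x 3 features with a hand-checkable pattern."""
    mz = np.array([200.1234, 450.5, 900.0])
    matrix = np.array(
        [
            [1.0, 0.0, 5.0],
            [2.0, 0.0, 0.0],
            [0.0, 3.0, 5.0],
            [4.0, 0.0, 5.0],
        ]
    )
    pixels = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    return FeatureTable(mz, matrix, pixels)


def random_table(rng: np.random.Generator, n_x=12, n_y=4, n_feat=8, density=0.4) -> FeatureTable:
    matrix = rng.uniform(0.1, 5.0, (n_x * n_y, n_feat))
    matrix[rng.random(matrix.shape) > density] = 0.0
    pixels = np.array([(x, y) for x in range(n_x) for y in range(n_y)])
    mz = np.sort(rng.uniform(150.0, 1000.0, n_feat))
    while np.any(np.diff(mz) <= 0):  # pragma: no cover - vanishing probability
        mz = np.sort(rng.uniform(150.0, 1000.0, n_feat))
    return FeatureTable(mz, matrix, pixels)


@pytest.fixture(scope="session")
def default_scene():
    """One realization of the default stratified scene (seed 42), cached."""
    config = make_default_scene(42)
    dataset, mask, truth = generate(config)
    return config, dataset, mask, truth


@pytest.fixture
def tiny_mask() -> VoidMask:
    labels = np.full((4, 2), SEDIMENT, dtype=np.int8)
    labels[1, 1] = VOID
    return VoidMask(labels)
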