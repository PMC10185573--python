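"""Shared fixtures: wavelength grids, simulator parameter sets, small
calibration tables, and a small trained cascade reused across test modules.
All fixtures are deterministic (fixed seeds)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from optodeml import (
    GBTConfig,
    SpectralModelParams,
    WavelengthGrid,
    generate_calibration_set,
    train_cascade,
)
from optodeml.prep import split_table


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def params() -> SpectralModelParams:
    return SpectralModelParams()


@pytest.fixture(scope="session")
def noiseless_params(params) -> SpectralModelParams:
    return dataclasses.replace(params, noise_sd=0.0, base_band=None)


@pytest.fixture(scope="session")
def no_crosstalk_params(params) -> SpectralModelParams:
    return dataclasses.replace(
        params, crosstalk_acid=0.0, crosstalk_ref=0.0, noise_sd=0.0, base_band=None
    )


@pytest.fixture(scope="session")
def small_cfg() -> GBTConfig:
    """Reduced ensemble for fast unit tests (not the tuned defaults)."""
    return GBTConfig(n_estimators=40, max_depth=5, min_child_weight=3,
                     learning_rate=0.2, seed=0)


@pytest.fixture(scope="session")
def small_noisy_table(params, grid):
    """Noisy calibration table over a coarse (pH, pO2) grid; ~384 rows."""
    return generate_calibration_set(
        ph_points=np.arange(4.0, 11.1, 1.0),
        po2_points=np.linspace(0.0, 195.0, 6),
        counts=8,
        params=params,
        grid=grid,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_split(small_noisy_table):
    return split_table(small_noisy_table, ratio=0.8, seed=5)


@pytest.fixture(scope="session")
def small_cascade(small_split, small_cfg):
    train, _ = small_split
    return train_cascade(train, cfg_ph=small_cfg, cfg_o2=small_cfg)
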