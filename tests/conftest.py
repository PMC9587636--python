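"""Shared fixtures: small synthetic screens generated in memory or on disk."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sopra.simulate import SimConfig, simulate_cell_table

TINY = dict(
    n_plates=1,
    n_wells=24,
    n_replicates=3,
    n_neutral=4,
    n_mock=1,
    n_positive=2,
    objects_mean=120.0,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_screen(tiny_config) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One small simulated screen: (cell table, ground truth)."""
    return simulate_cell_table(tiny_config)


@pytest.fixture(scope="session")
def tiny_cells(tiny_screen) -> pd.DataFrame:
    return tiny_screen[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
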