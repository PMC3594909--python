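"""Shared fixtures: small synthetic tables at fixed seeds."""

import numpy as np
import pytest

from metaboclass import FeatureTable, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def signal_table() -> FeatureTable:
    """Balanced two-group table with a clear effect (n=100, p=30, d=2)."""
    cfg = SimConfig(
        n_group0=50, n_group1=50, p=30, n_informative=6, effect_size=2.0,
        block_size=5, block_rho=0.3, n_identified=10, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_table() -> FeatureTable:
    """Same dimensions as signal_table but with no group effect."""
    cfg = SimConfig(
        n_group0=50, n_group1=50, p=30, n_informative=0, effect_size=0.0,
        block_size=5, block_rho=0.3, n_identified=10, seed=12,
    )
    return generate_dataset(cfg)


@pytest.fixture
def tiny_table() -> FeatureTable:
    """Hand-built 6 x 3 table with known values."""
    return FeatureTable(
        values=np.array(
            [[2.0, 3.0, 5.0], [1.0, 1.0, 2.0], [4.0, 2.0, 4.0],
             [5.0, 6.0, 9.0], [6.0, 5.0, 9.0], [7.0, 8.0, 15.0]]
        ),
        sample_ids=[f"s{i}" for i in range(6)],
        variable_ids=["va", "vb", "vc"],
        groups=["0", "0", "0", "1", "1", "1"],
    )
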