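import numpy as np
import pytest

from covnet import (DensityGrid, SyntheticConfig, compute_association_matrix,
                    generate_volume_table)


@pytest.fixture(scope="session")
def default_table():
    """Study-shaped synthetic table: 34 + 28 subjects, 92 regions."""
    return generate_volume_table(SyntheticConfig(seed=1234))


@pytest.fixture(scope="session")
def small_table():
    """Small, fast table for pipeline-level tests."""
    cfg = SyntheticConfig(n_regions=30, n_subjects_a=20, n_subjects_b=18,
                          n_modules=5, seed=11)
    return generate_volume_table(cfg)


@pytest.fixture(scope="session")
def default_assoc(default_table):
    return compute_association_matrix(default_table, "A")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_grid():
    return DensityGrid.regular()
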