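import numpy as np
import pytest

import relsim as rs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_map():
    """Two linear chromosomes, 100 cM male / 157 cM female each."""
    return rs.make_synthetic_map(
        n_chrom=2, phys_len=100_000_000, male_len=100.0, female_factor=1.57,
        n_knots=11, roughness=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def rough_map():
    """Four chromosomes with locally varying male/female rates."""
    return rs.make_synthetic_map(
        n_chrom=4, phys_len=120_000_000, male_len=90.0, female_factor=1.57,
        n_knots=25, roughness=0.4, seed=2,
    )


@pytest.fixture(scope="session")
def single_chrom_map():
    """One linear chromosome of 2.8 sex-averaged Morgans (no dimorphism)."""
    return rs.make_synthetic_map(
        n_chrom=1, phys_len=250_000_000, male_len=280.0, female_factor=1.0,
        n_knots=2, roughness=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def intf_params():
    return rs.SexedInterferenceParams()
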