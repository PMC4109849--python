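import numpy as np
import pandas as pd
import pytest

from tagen import TelegraphParams, make_telegraph_population


@pytest.fixture
def noiseless_on() -> TelegraphParams:
    """Locked-active promoter with every noise source switched off."""
    return TelegraphParams(lock_mode="locked_on", mu_on=100.0, mu_off=5.0,
                           cv_intrinsic=0.0, sigma_extrinsic=0.0,
                           cv_measurement=0.0)


@pytest.fixture
def default_params() -> TelegraphParams:
    return TelegraphParams(k_on=0.1, k_off=0.1, mu_on=100.0, mu_off=5.0,
                           cv_intrinsic=0.1, sigma_extrinsic=0.1,
                           cv_measurement=0.1)


@pytest.fixture
def two_channel_cells(default_params) -> pd.DataFrame:
    return make_telegraph_population(default_params, 2_000, seed=42, n_alleles=2)


@pytest.fixture
def random_cell_table():
    """Factory for small random two-channel tables (positive intensities)."""

    def make(seed: int, n: int = 40) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "population_id": "p0",
            "channel1_intensity": rng.lognormal(3.0, 0.5, n),
            "channel2_intensity": rng.lognormal(3.0, 0.5, n),
        })

    return make
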