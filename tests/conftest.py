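import numpy as np
import pytest

from epiphi import GridConfig, run_grid


@pytest.fixture(scope="session")
def default_grid():
    """Full factorial study grid: 450 combinations x 10 replicates of n=10,000."""
    return run_grid(GridConfig(replicates=10, master_seed=20240620))


@pytest.fixture(scope="session")
def small_grid():
    """Reduced grid for fast regression-machinery tests."""
    cfg = GridConfig(
        rho_values=[0.0, 0.3],
        d_values=[0.1, 0.2, 0.4],
        ir_values=[0.1, 0.2, 0.4],
        rr_values=[0.5, 1.0, 2.0, 5.0, 10.0],
        n=2_000,
        replicates=3,
        master_seed=99,
    )
    return run_grid(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
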