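import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from raygrowth.simulate import (SimulationConfig, simulate_double_reads,
                                simulate_population)


@pytest.fixture(scope="session")
def noise_free_ds():
    """Single-sex noise-free population captured at the deposition month,
    so capture sizes sit exactly on the true growth curve."""
    cfg = SimulationConfig(
        n_fish=40, sex_ratio=1.0, growth_sd=0.0, vr_sd=0.0,
        read_error_prob=0.0, selectivity=None,
        sampling_months=[(2023, 12)], seed=7)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_ds():
    """Two-sex population with default noise and a second reading session."""
    cfg = SimulationConfig(n_fish=120, seed=11)
    return simulate_double_reads(simulate_population(cfg))
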