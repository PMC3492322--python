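import numpy as np
import pandas as pd
import pytest

from ctcseq.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Default cohort with all noise off: planted values are exact."""
    config = SimulationConfig(seed=11, heterogeneity_sd=0.0, patient_effect_sd=0.0)
    return simulate_expression(config)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default cohort at the standard heterogeneity settings."""
    return simulate_expression(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def small_fpkm():
    """Tiny genes x samples frame with hand-checkable rankings."""
    return pd.DataFrame(
        {
            "s1": [9.0, 7.0, 5.0, 3.0, 1.0],
            "s2": [1.0, 3.0, 5.0, 7.0, 9.0],
        },
        index=["gA", "gB", "gC", "gD", "gE"],
    )
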