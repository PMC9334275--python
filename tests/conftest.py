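import pytest
from hypothesis import HealthCheck, settings

import thermvar as tv

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Rearing temperatures of the thermal-performance experiment.
TPC_DESIGN_TEMPS = [17.0, 19.0, 22.0, 25.0, 28.0]


@pytest.fixture(scope="session")
def reference_tpc():
    """Published point estimates used as the reference parameter set."""
    return tv.REFERENCE_TPC


@pytest.fixture(scope="session")
def high_regime():
    """High-amplitude fluctuation: 20-26 °C, two-week cycles, 12-h ramps."""
    return tv.make_regime(tv.TREATMENT_REGIMES["high"])


@pytest.fixture(scope="session")
def noiseless_obs(reference_tpc):
    """Noise-free growth observations on the five-temperature design."""
    return tv.simulate_single_growth(
        20, TPC_DESIGN_TEMPS, reference_tpc, noise_sd=0.0, seed=1
    )


@pytest.fixture(scope="session")
def seeded_interaction(reference_tpc):
    """One seeded four-treatment synthetic interaction experiment."""
    return tv.simulate_interaction_experiment(reference_tpc, seed=11)
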