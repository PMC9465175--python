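import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mitoprofile.simulate import SimulationConfig, generate


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic mitogenome, seed 1: (genome, table, manifest)."""
    return generate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sims_1_to_5():
    """Synthetic mitogenomes for seeds 1-5 (round-trip recovery substrate)."""
    return {seed: generate(SimulationConfig(seed=seed)) for seed in range(1, 6)}
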