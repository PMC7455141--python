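import pytest
from hypothesis import HealthCheck, settings

import primsite as p

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> p.SimulationConfig:
    return p.SimulationConfig(
        seed=42, n_chromosomes=2, chromosome_lengths=100_000,
        n_integrations=30, n_genes=10,
    )


@pytest.fixture(scope="session")
def small_genome(small_config) -> p.ReferenceGenome:
    return p.generate_genome(small_config)


@pytest.fixture(scope="session")
def transposon() -> p.TransposonModel:
    return p.sb100x_transposon(total_length=11_800, avoid_motif="GAGCTC")
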