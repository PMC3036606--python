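import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20110117)


@pytest.fixture(scope="session")
def small_contig_set():
    """A modest forced-SSR contig set shared across tests."""
    from genicssr.synthetic import GeneratorConfig, generate_contig_set

    config = GeneratorConfig(n_contigs=120, ssr_probability=1.0, seed=11)
    contigs, truth = generate_contig_set(config)
    return contigs, truth
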