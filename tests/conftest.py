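import dataclasses

import pytest

from tagdge.simulate import SimConfig, simulate_transcriptome, simulate_tag_libraries


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return dataclasses.replace(
        SimConfig(),
        n_genes=50,
        transcript_length_range=(100, 500),
        n_de_genes=5,
        library_depth=5000,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_transcriptome(small_config)


@pytest.fixture(scope="session")
def small_pair(small_config, small_bundle):
    return simulate_tag_libraries(small_config, small_bundle)


@pytest.fixture(scope="session")
def noise_free_config(small_config) -> SimConfig:
    return dataclasses.replace(
        small_config, error_rate=0.0, n_read_fraction=0.0, adaptor_only_fraction=0.0
    )


@pytest.fixture(scope="session")
def noise_free_pair(noise_free_config, small_bundle):
    return simulate_tag_libraries(noise_free_config, small_bundle)
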