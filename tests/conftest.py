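import pytest

from sheepmove import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(moves_per_year=400, years=(2017, 2018), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(premises, parishes, census, batch, reads, truth) for fast tests."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No mis-reads, no batch-only sheep: read records are exhaustive."""
    return SimConfig(moves_per_year=400, years=(2017,), p_misread=0.0,
                     p_batch_only_sheep=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_dataset(clean_config)
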