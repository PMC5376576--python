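import pytest

from mirfuse.simulate import (
    SimConfig,
    gen_degradome,
    gen_hormone_panel,
    gen_reference,
    gen_sread_libraries,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def refs(sim_config):
    return gen_reference(sim_config)


@pytest.fixture(scope="session")
def libraries_truth(sim_config, refs):
    return gen_sread_libraries(sim_config, refs)


@pytest.fixture(scope="session")
def libraries(libraries_truth):
    return libraries_truth[0]


@pytest.fixture(scope="session")
def truth(libraries_truth):
    return libraries_truth[1]


@pytest.fixture(scope="session")
def degradome_tags(sim_config, refs, truth):
    return gen_degradome(sim_config, refs, truth)


@pytest.fixture(scope="session")
def hormone_panel(sim_config, truth):
    return gen_hormone_panel(sim_config, truth)
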