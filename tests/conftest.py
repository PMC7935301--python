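import pytest

from mrmvalid import cli_io, synthetic_data


@pytest.fixture(scope="session")
def default_sim_config():
    return synthetic_data.default_config(seed=0)


@pytest.fixture(scope="session")
def default_records(default_sim_config):
    return synthetic_data.simulate_all(default_sim_config)


@pytest.fixture(scope="session")
def default_bundle(default_sim_config, default_records):
    return cli_io.run_full_validation(cli_io.AssayConfig(), default_records)
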