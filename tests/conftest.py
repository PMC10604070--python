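import pytest

from disquad import synthetic_data as synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SyntheticConfig(n_proteins=12, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synth.generate(small_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_dataset):
    d = tmp_path_factory.mktemp("fixture")
    synth.write_fixture(small_dataset, d)
    return d
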