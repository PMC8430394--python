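import pytest

from nsclc_cea import make_fixture_config, run_base_case, run_psa


@pytest.fixture(scope="session")
def config():
    return make_fixture_config()


@pytest.fixture(scope="session")
def base_case(config):
    return run_base_case(config)


@pytest.fixture(scope="session")
def psa_1000(config):
    """The full 1,000-draw probabilistic sensitivity analysis (shared)."""
    return run_psa(config, n_iterations=1000, seed=227)
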