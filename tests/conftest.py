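import pytest

from parafate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def clean_scenario():
    """A mid-sized zero-noise scenario shared across read-only tests."""
    return generate_scenario(ScenarioConfig(seed=11))


@pytest.fixture()
def tiny_config():
    """A small scenario configuration for brute-force comparisons."""
    return ScenarioConfig(
        seed=3,
        n_families=8,
        n_singletons=4,
        n_retrotransposon_families=1,
        retro_family_size=4,
    )
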