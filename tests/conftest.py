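import pytest
from hypothesis import settings

from nppm import RuleTable, default_config, generate_products

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rules():
    return RuleTable.default()


@pytest.fixture(scope="session")
def small_survey():
    """A 200-product synthetic survey with its ground-truth ledger."""
    config = default_config()
    config.n = 200
    config.seed = 7
    return generate_products(config)
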