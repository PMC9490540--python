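import pytest

from medtweet import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(n_accounts=400, seed=42)


@pytest.fixture(scope="session")
def corpus(default_config):
    """A seeded 400-account corpus with all trap kinds realized."""
    accounts, tweets = generate_corpus(default_config)
    return accounts, tweets


@pytest.fixture(scope="session")
def truth(corpus):
    accounts, _ = corpus
    return {a.account_id: a.true_label == "physician" for a in accounts}
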