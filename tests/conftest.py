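import warnings

import pytest

from ontofeat.mapping import map_corpus
from ontofeat.synth import GeneratorConfig, generate, mini_ontology

# sklearn emits fold-population warnings for the cohort's n=1 labels; they are expected
warnings.filterwarnings("ignore", message="The least populated class")


@pytest.fixture(scope="session")
def fixture_ontology():
    return mini_ontology()


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: no vocabulary steering, modest size."""
    return GeneratorConfig(n_patients=60, target_vocab=None, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_mapping(small_corpus):
    reports, truth, ontology = small_corpus
    return map_corpus(reports, ontology)
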