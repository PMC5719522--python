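import pytest

from gprelex.corpus_io import default_lexicon
from gprelex.synthetic_corpus import GeneratorConfig, generate_corpus, worked_example


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture()
def fig_sentence():
    """'The association of Genotype1 with Phenotype2 is confirmed.'"""
    return worked_example()


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(n_sentences=60, seed=11))
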