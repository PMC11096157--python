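import pytest

from fedbionlp.corpus_io import Corpus
from fedbionlp.experiments import bio_tag_list
from fedbionlp.models import build_vocab
from fedbionlp.synthetic import GenConfig, generate_ner, generate_re, make_sources


@pytest.fixture(scope="session")
def source():
    return make_sources(1, 1.0, seed=5)[0]


@pytest.fixture(scope="session")
def two_sources_disjoint():
    return make_sources(2, 0.0, seed=1)


@pytest.fixture(scope="session")
def ner_corpus(source) -> Corpus:
    return generate_ner(source, GenConfig(n_sentences=60, tag_noise_rate=0.0, seed=2))


@pytest.fixture(scope="session")
def re_corpus(source) -> Corpus:
    return generate_re(source, GenConfig(n_sentences=60, seed=2))


@pytest.fixture(scope="session")
def ner_vocab(ner_corpus):
    return build_vocab([ner_corpus])


@pytest.fixture(scope="session")
def tag_inventory(ner_corpus):
    return bio_tag_list(ner_corpus.type_inventory)
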