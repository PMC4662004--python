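import numpy as np
import pytest

from topicscreen import (
    Corpus,
    LabeledDocument,
    LDAConfig,
    SyntheticSpec,
    generate_screening_corpus,
)


@pytest.fixture(scope="session")
def toy_corpus() -> Corpus:
    """Three preprocessed documents with hand-countable token frequencies.

    Frequencies: screening 3, review 2, topic 2, model 2, corpus 1 (hapax),
    zebra 1 (hapax).
    """
    docs = [
        LabeledDocument("d1", tokens=["screening", "review", "topic"],
                        label="relevant"),
        LabeledDocument("d2", tokens=["screening", "review", "model"],
                        label="irrelevant"),
        LabeledDocument("d3", tokens=["screening", "topic", "model",
                                      "corpus", "zebra"],
                        label="irrelevant"),
    ]
    c = Corpus(documents=docs)
    c.build_vocabulary()
    return c


@pytest.fixture(scope="session")
def small_screening_corpus():
    """Desk-scale labelled corpus: separable classes, 10% prevalence.

    Uses a deliberately small vocabulary so BOW paths stay fast; the
    high-dimensional regime is exercised in the acceptance tests.
    """
    spec = SyntheticSpec(
        K=6, V=400, n_docs=240, mean_doc_len=40, beta=0.05,
        prevalence=0.1, class_concentration=8.0, seed=11,
    )
    return generate_screening_corpus(spec)


@pytest.fixture(scope="session")
def quick_lda_config():
    return LDAConfig(n_topics=6, iterations=150, burn_in=50, thin=5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
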