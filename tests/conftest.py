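import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import readtopics as rt

settings.register_profile(
    "default", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def stopwords():
    return rt.default_stopwords()


@pytest.fixture(scope="session")
def undesirable():
    return rt.default_undesirable()


@pytest.fixture(scope="session")
def gold_backend():
    """The packaged two-sense WordNet 2.1 entry for 'gold'."""
    return rt.packaged_gold_senses()


@pytest.fixture(scope="session")
def worked_example():
    """The printed ranked topic list and gold standard of the evaluation example."""
    ranked = ["bank", "company", "rates", "dollar", "Canada",
              "oil", "sand", "Alberta", "exploitation", "financing"]
    ranking = [(item, float(10 - i)) for i, item in enumerate(ranked)]
    gold = {"dollar", "price", "corporation", "oil", "business", "bank"}
    return ranking, gold


@pytest.fixture(scope="session")
def regression_corpus():
    """The seeded regression corpus: 3 themes x 4 words, 2 shared items, 60% theme tokens."""
    return rt.generate_corpus(rt.SynthSpec())


def random_toy_fixture(seed: int, n_docs: int = 1, doc_length: int = 40):
    """An arbitrary small lexicon plus random documents over its vocabulary.

    Words map to overlapping item lists so that frequency rankings have real
    structure (shared items, ties); used by the dual-route oracle checks.
    """
    rng = np.random.default_rng(seed)
    n_words = int(rng.integers(5, 15))
    n_items = int(rng.integers(4, 12))
    vocabulary = [f"w{i}" for i in range(n_words)]
    item_pool = [f"i{i}" for i in range(n_items)]
    entries = {}
    for word in vocabulary:
        k = int(rng.integers(1, min(5, n_items) + 1))
        picks = rng.choice(n_items, size=k, replace=False)
        entries[word] = [item_pool[i] for i in picks]
    lexicon = rt.ToyLexicon(entries=entries)
    docs = [
        [vocabulary[i] for i in rng.integers(0, n_words, size=doc_length)]
        for _ in range(n_docs)
    ]
    return lexicon, docs
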