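import numpy as np
import pytest

from sectionseer.corpus_io import CANONICAL_LABELS, Abstract, Corpus, Sentence
from sectionseer.synthetic_corpus import default_spec, generate_corpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two hand-written abstracts, 3 + 2 sentences, all five labels."""
    a1 = Abstract(
        "1001",
        [
            Sentence(("the", "study", "background"), "BACKGROUND", 0),
            Sentence(("we", "aimed", "to", "test"), "OBJECTIVE", 1),
            Sentence(("patients", "were", "randomized"), "METHODS", 2),
        ],
    )
    a2 = Abstract(
        "1002",
        [
            Sentence(("pain", "scores", "fell"), "RESULTS", 0),
            Sentence(("aspirin", "works"), "CONCLUSIONS", 1),
        ],
    )
    return Corpus([a1, a2], CANONICAL_LABELS)


@pytest.fixture(scope="session")
def small_corpus() -> Corpus:
    """Session-wide small synthetic corpus (~500 abstracts)."""
    return generate_corpus(default_spec("small"), seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
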