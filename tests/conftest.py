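import numpy as np
import pytest

from speechmarkers.coherence import EmbeddingLexicon
from speechmarkers.simulate import gen_cohort, sample1_like
from speechmarkers.syntax import LexiconTagger
from speechmarkers.transcripts import FilterConfig, tokenize


def make_transcript(sentences, *, version="manual", participant_id="P1", excerpt_id="1",
                    filter_cfg=None):
    """Transcript from a list of sentence strings (periods appended)."""
    raw = " ".join(s.rstrip(".") + "." for s in sentences)
    return tokenize(raw, filter_cfg, participant_id=participant_id,
                    excerpt_id=excerpt_id, version=version)


@pytest.fixture(scope="session")
def unit_lexicon():
    """Orthonormal 2-d lexicon with equal word probabilities.

    SIF weighting is a common scalar here, so cosines between embeddings
    equal cosines between the raw construction vectors.
    """
    vectors = {
        "east": np.array([1.0, 0.0]),
        "north": np.array([0.0, 1.0]),
        "west": np.array([-1.0, 0.0]),
        "cat": np.array([1.0, 0.0]),
        "dog": np.array([0.8, 0.6]),
    }
    probs = {w: 0.2 for w in vectors}
    return EmbeddingLexicon(vectors=vectors, probs=probs, dim=2)


@pytest.fixture(scope="session")
def dict_tagger():
    return LexiconTagger(
        {"the": "DT", "cat": "NN", "is": "VBZ", "under": "IN", "table": "NN",
         "my": "PRP$", "i": "PRP", "which": "WDT", "who": "WP", "where": "WRB",
         "bigger": "JJR"},
        default="NN",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12-participant cohort, both transcript versions, fixed seed."""
    cfg = sample1_like(n_participants=12, rng_seed=42)
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_tagger(small_cohort):
    return LexiconTagger(small_cohort.lexicon.tags)
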