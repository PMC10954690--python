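"""Scikit-learn-style marker extractors over lists of transcripts.

Each featurizer is a stateless transformer (``fit`` validates and returns
``self``; ``transform`` maps a sequence of :class:`~speechmarkers.transcripts.
Transcript` objects to a DataFrame of markers), so the extractors compose
with sklearn pipelines and ``get_params``/``set_params`` grid search.
:func:`extract_markers` runs all three marker families and returns the tidy
excerpt-level table the statistical pipeline consumes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .coherence import SEMANTIC_MEASURES, EmbeddingLexicon, semantic_measures
from .graphs import GRAPH_MEASURES, GraphConfig, shuffle_null, windowed_measures
from .syntax import SYNTACTIC_MEASURES, EnglishRuleTagger, Tagger, tag, tag_frequencies
from .transcripts import FilterConfig, Transcript

__all__ = [
    "SpeechGraphFeaturizer",
    "SemanticCoherenceFeaturizer",
    "SyntacticFeaturizer",
    "extract_markers",
    "MARKER_COLUMNS",
]

#: Column order of the full excerpt-level marker table.
MARKER_COLUMNS = tuple(GRAPH_MEASURES) + tuple(SEMANTIC_MEASURES) + tuple(SYNTACTIC_MEASURES)


def _check_transcripts(X: Sequence[Transcript]) -> list[Transcript]:
    X = list(X)
    if not X:
        raise ValueError("empty transcript collection")
    if not all(isinstance(t, Transcript) for t in X):
        raise TypeError("X must be a sequence of Transcript objects")
    return X


def _index_frame(X: Sequence[Transcript], rows: list[dict]) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in X],
            "excerpt_id": [t.excerpt_id for t in X],
            "version": [t.version for t in X],
        }
    )
    return pd.concat([meta, pd.DataFrame(rows)], axis=1)


class SpeechGraphFeaturizer(TransformerMixin, BaseEstimator):
    """Windowed word-graph connectivity measures per transcript.

    Parameters mirror the graph configuration: 30-word windows advancing by
    15 words, measures averaged across windows.  With ``include_z=True`` a
    ``<measure>_z`` column per measure is added from the ``n_shuffles``-word-
    permutation null (slower by a factor of ``n_shuffles``).
    """

    def __init__(
        self,
        window_size: int = 30,
        window_step: int = 15,
        include_z: bool = False,
        n_shuffles: int = 100,
        random_state: int = 0,
    ) -> None:
        self.window_size = window_size
        self.window_step = window_step
        self.include_z = include_z
        self.n_shuffles = n_shuffles
        self.random_state = random_state

    def _config(self) -> GraphConfig:
        return GraphConfig(
            window_size=self.window_size,
            window_step=self.window_step,
            n_shuffles=self.n_shuffles,
            rng_seed=self.random_state,
        )

    def fit(self, X: Sequence[Transcript], y=None) -> "SpeechGraphFeaturizer":
        self._config()  # validates parameters
        _check_transcripts(X)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[Transcript]) -> pd.DataFrame:
        X = _check_transcripts(X)
        cfg = self._config()
        rows = []
        for t in X:
            if self.include_z:
                null = shuffle_null(t.tokens, cfg)
                row = null.observed.as_dict()
                row.update({f"{k}_z": v for k, v in null.z.items()})
            else:
                row = windowed_measures(t.tokens, cfg).as_dict()
            rows.append(row)
        return _index_frame(X, rows)

    def get_feature_names_out(self, input_features=None):
        names = list(GRAPH_MEASURES)
        if self.include_z:
            names += [f"{m}_z" for m in GRAPH_MEASURES]
        return np.asarray(names, dtype=object)


class SemanticCoherenceFeaturizer(TransformerMixin, BaseEstimator):
    """SIF-embedding coherence statistics per transcript.

    ``lexicon`` maps words to vectors/probabilities; ``stimuli`` maps each
    excerpt id to its a-priori stimulus description text.
    """

    def __init__(
        self,
        lexicon: EmbeddingLexicon | None = None,
        stimuli: Mapping[str, str] | None = None,
        filter_config: FilterConfig | None = None,
        remove_pc: bool = False,
    ) -> None:
        self.lexicon = lexicon
        self.stimuli = stimuli
        self.filter_config = filter_config
        self.remove_pc = remove_pc

    def fit(self, X: Sequence[Transcript], y=None) -> "SemanticCoherenceFeaturizer":
        if self.lexicon is None or self.stimuli is None:
            raise ValueError("lexicon and stimuli are required")
        _check_transcripts(X)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[Transcript]) -> pd.DataFrame:
        if self.lexicon is None or self.stimuli is None:
            raise ValueError("lexicon and stimuli are required")
        X = _check_transcripts(X)
        rows = []
        for t in X:
            m = semantic_measures(
                t,
                self.lexicon,
                self.stimuli[t.excerpt_id],
                filter_cfg=self.filter_config,
                remove_pc=self.remove_pc,
            )
            rows.append(m.as_dict())
        return _index_frame(X, rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(list(SEMANTIC_MEASURES) + ["n_dropped_sentences"], dtype=object)


class SyntacticFeaturizer(TransformerMixin, BaseEstimator):
    """POS-tag category counts per transcript (raw counts; verbosity-tracking
    by design, with per-word rates available via ``include_rates``)."""

    def __init__(self, tagger: Tagger | None = None, include_rates: bool = False) -> None:
        self.tagger = tagger
        self.include_rates = include_rates

    def fit(self, X: Sequence[Transcript], y=None) -> "SyntacticFeaturizer":
        _check_transcripts(X)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[Transcript]) -> pd.DataFrame:
        X = _check_transcripts(X)
        tagger = self.tagger or EnglishRuleTagger()
        rows = [
            tag_frequencies(tag(t, tagger)).as_dict(rates=self.include_rates) for t in X
        ]
        return _index_frame(X, rows)

    def get_feature_names_out(self, input_features=None):
        names = list(SYNTACTIC_MEASURES)
        if self.include_rates:
            names += [f"{m}_rate" for m in SYNTACTIC_MEASURES[1:]]
        return np.asarray(names, dtype=object)


def extract_markers(
    transcripts: Sequence[Transcript],
    lexicon: EmbeddingLexicon,
    stimuli: Mapping[str, str],
    *,
    graph: SpeechGraphFeaturizer | None = None,
    tagger: Tagger | None = None,
    filter_config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Full excerpt-level marker table: one row per transcript, all marker
    families as columns."""
    graph = graph or SpeechGraphFeaturizer()
    sem = SemanticCoherenceFeaturizer(lexicon=lexicon, stimuli=stimuli,
                                      filter_config=filter_config)
    syn = SyntacticFeaturizer(tagger=tagger)
    keys = ["participant_id", "excerpt_id", "version"]
    g = graph.fit(transcripts).transform(transcripts)
    s = sem.fit(transcripts).transform(transcripts).drop(columns=keys)
    y = syn.fit(transcripts).transform(transcripts).drop(columns=keys)
    return pd.concat([g, s, y], axis=1)


def extract_cohort(cohort, *, graph: SpeechGraphFeaturizer | None = None) -> pd.DataFrame:
    """Excerpt-level marker table for a synthetic cohort, using the cohort's
    own embedding lexicon, stimuli and word→tag dictionary."""
    from .syntax import LexiconTagger

    lex = cohort.lexicon
    return extract_markers(
        cohort.transcripts,
        lex.lexicon,
        lex.stimuli,
        graph=graph,
        tagger=LexiconTagger(lex.tags),
    )
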