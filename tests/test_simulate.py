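import dataclasses

import numpy as np
import pytest

from speechmarkers.coherence import cosine, load_embeddings
from speechmarkers.graphs import build_graph, graph_measures
from speechmarkers.quality import align, quality_metrics
from speechmarkers.simulate import (
    GeneratorConfig,
    corrupt_transcript,
    gen_cohort,
    gen_lexicon,
    gen_transcript,
    sample1_like,
    sample2_like,
    write_cohort,
)
from speechmarkers.transcripts import load_corpus, read_transcripts


def rng(seed=0):
    return np.random.default_rng(seed)


class TestGenLexicon:
    def test_within_topic_cosine_exceeds_between(self):
        cfg = GeneratorConfig(n_topics=2, vocab_per_topic=20, embedding_dim=4)
        lex = gen_lexicon(cfg, rng())
        vecs = lex.lexicon.vectors
        within, between = [], []
        for t, words in enumerate(lex.topic_words):
            others = lex.topic_words[1 - t]
            ws = words.tolist()
            within += [cosine(vecs[a], vecs[b]) for a, b in zip(ws, ws[1:])]
            between += [cosine(vecs[a], vecs[b]) for a, b in zip(ws, others.tolist())]
        assert np.mean(within) > np.mean(between) + 0.3

    def test_seed_reproducibility(self):
        cfg = GeneratorConfig()
        a = gen_lexicon(cfg, rng(7))
        b = gen_lexicon(cfg, rng(7))
        assert a.stimuli == b.stimuli
        assert a.tags == b.tags
        for w in a.lexicon.vectors:
            assert np.array_equal(a.lexicon.vectors[w], b.lexicon.vectors[w])

    def test_dim_smaller_than_topics_rejected(self):
        with pytest.raises(ValueError, match="separated"):
            gen_lexicon(GeneratorConfig(embedding_dim=1, n_topics=3), rng())

    def test_probabilities_are_zipf_like_and_normalized(self):
        lex = gen_lexicon(GeneratorConfig(), rng())
        p = np.array(list(lex.lexicon.probs.values()))
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()


class TestGenTranscript:
    def test_zero_drift_stays_on_stimulus_topic(self):
        cfg = GeneratorConfig(drift_intercept=0.0, drift_slope=0.0, filler_rate=0.0)
        lex = gen_lexicon(cfg, rng())
        t = gen_transcript(0.0, "1", lex, cfg, rng(1))
        topic = lex.excerpt_topic["1"]
        assert all(tok.startswith(f"t{topic:02d}") for tok in t.tokens)

    def test_zero_repeat_probability_means_no_self_loops(self):
        cfg = GeneratorConfig(repeat_intercept=0.0, repeat_slope=0.0, filler_rate=0.0)
        lex = gen_lexicon(cfg, rng())
        for seed in range(5):
            t = gen_transcript(0.5, "2", lex, cfg, rng(seed))
            assert graph_measures(build_graph(t.tokens)).l1 == 0

    def test_seed_determinism(self):
        cfg = GeneratorConfig()
        lex = gen_lexicon(cfg, rng())
        a = gen_transcript(1.0, "3", lex, cfg, rng(9))
        b = gen_transcript(1.0, "3", lex, cfg, rng(9))
        assert a.raw_text == b.raw_text

    def test_word_count_tracks_configuration(self):
        cfg = GeneratorConfig(words_per_excerpt_mean=120, words_per_excerpt_sd=10)
        lex = gen_lexicon(cfg, rng())
        counts = [gen_transcript(0.0, "1", lex, cfg, rng(s)).n_words for s in range(30)]
        assert 100 < np.mean(counts) < 140

    def test_higher_theta_lowers_stimulus_similarity(self):
        # monotone plant: drift grows with theta, on-topic falls
        cfg = GeneratorConfig(drift_intercept=0.1, drift_slope=0.2, filler_rate=0.0)
        lex = gen_lexicon(cfg, rng())
        topic = lex.excerpt_topic["1"]

        def on_topic_word_share(theta, n=60):
            r = rng(int(100 + theta * 10))
            share = []
            for _ in range(n):
                t = gen_transcript(theta, "1", lex, cfg, r)
                toks = t.tokens
                share.append(np.mean([tok.startswith(f"t{topic:02d}") for tok in toks]))
            return np.mean(share)

        assert on_topic_word_share(-1.0) > on_topic_word_share(1.0) + 0.1


class TestCorruptTranscript:
    def test_zero_rate_is_identity(self):
        cfg = GeneratorConfig(asr_error_rate=0.0, punct_error_rate=0.0)
        lex = gen_lexicon(cfg, rng())
        t = gen_transcript(0.0, "1", lex, cfg, rng(2))
        auto, counts = corrupt_transcript(t, lex, cfg, rng(3))
        assert auto.tokens == t.tokens
        assert quality_metrics(align(t.tokens, auto.tokens)).wer == 0.0
        assert sum(counts.values()) == 0

    def test_deletion_only_mix_never_lengthens(self):
        cfg = GeneratorConfig(asr_error_rate=0.3, sub_del_ins_mix=(0.0, 1.0, 0.0),
                              punct_error_rate=0.0)
        lex = gen_lexicon(cfg, rng())
        for seed in range(5):
            t = gen_transcript(0.0, "1", lex, cfg, rng(seed))
            auto, counts = corrupt_transcript(t, lex, cfg, rng(seed + 50))
            assert auto.n_words <= t.n_words
            assert counts["substitutions"] == counts["insertions"] == 0

    def test_measured_wer_tracks_nominal_rate(self):
        cfg = GeneratorConfig(asr_error_rate=0.2, punct_error_rate=0.0)
        lex = gen_lexicon(cfg, rng())
        r = rng(11)
        wers = []
        for _ in range(40):
            t = gen_transcript(0.0, "1", lex, cfg, r)
            auto, _ = corrupt_transcript(t, lex, cfg, r)
            wers.append(quality_metrics(align(t.tokens, auto.tokens)).wer)
        assert np.mean(wers) == pytest.approx(0.2, abs=0.03)

    def test_punctuation_channel_changes_sentences_not_words(self):
        cfg = GeneratorConfig(asr_error_rate=0.0, punct_error_rate=0.5)
        lex = gen_lexicon(cfg, rng())
        t = gen_transcript(0.0, "1", lex, cfg, rng(4))
        auto, counts = corrupt_transcript(t, lex, cfg, rng(5))
        assert auto.tokens == t.tokens
        assert counts["punctuation"] > 0
        assert auto.n_sentences != t.n_sentences


class TestGenCohort:
    def test_transcript_count(self):
        cohort = gen_cohort(GeneratorConfig(n_participants=3, rng_seed=0))
        assert len(cohort.transcripts) == 3 * 8 * 2
        keys = {(t.participant_id, t.excerpt_id, t.version) for t in cohort.transcripts}
        assert len(keys) == 48  # every pair exists exactly once

    def test_seed_reproducibility(self):
        a = gen_cohort(GeneratorConfig(n_participants=3, rng_seed=5))
        b = gen_cohort(GeneratorConfig(n_participants=3, rng_seed=5))
        assert a.outcomes.equals(b.outcomes)
        assert [t.raw_text for t in a.transcripts] == [t.raw_text for t in b.transcripts]

    def test_outcomes_in_questionnaire_ranges(self, small_cohort):
        out = small_cohort.outcomes
        assert out.spq.between(0, 74).all()
        assert out.pdi.between(0, 21).all()
        assert out.age.between(18, 40).all()

    def test_loading_controls_theta_outcome_correlation(self):
        base = dict(n_participants=250, n_excerpts=1, words_per_excerpt_mean=20,
                    words_per_excerpt_sd=2)
        planted = gen_cohort(GeneratorConfig(spq_loading=3.0, rng_seed=1, **base))
        null = gen_cohort(GeneratorConfig(spq_loading=0.0, pdi_loading=0.0, rng_seed=1, **base))
        r_planted = np.corrcoef(planted.ground_truth.theta, planted.outcomes.spq)[0, 1]
        r_null = np.corrcoef(null.ground_truth.theta, null.outcomes.spq)[0, 1]
        assert r_planted > 0.5
        assert abs(r_null) < 0.15

    def test_presets_differ_only_in_channel(self):
        s1, s2 = sample1_like(), sample2_like()
        assert s1.asr_error_rate == 0.21 and s2.asr_error_rate == 0.08
        a, b = dataclasses.asdict(s1), dataclasses.asdict(s2)
        for k in ("asr_error_rate", "punct_error_rate"):
            a.pop(k), b.pop(k)
        assert a == b


class TestWriteCohort:
    def test_written_corpus_round_trips_through_loaders(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path)
        corpus = load_corpus(tmp_path / "manifest.csv", tmp_path / "outcomes.csv")
        assert len(corpus.transcripts) == len(small_cohort.transcripts)
        loaded = read_transcripts(corpus)
        assert loaded[0].tokens == small_cohort.transcripts[0].tokens
        lex = load_embeddings(tmp_path / "embeddings.txt", tmp_path / "word_freqs.csv")
        assert lex.vocab_size == small_cohort.lexicon.lexicon.vocab_size
        assert lex.dim == small_cohort.config.embedding_dim
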