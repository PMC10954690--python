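"""Synthetic speech-study cohorts with planted marker–symptom structure.

The study design being emulated: each participant describes 8 ambiguous
picture prompts for one minute each; recordings are transcribed both by a
human (``manual``) and a speech recognizer (``automated``), and participants
complete schizotypy (SPQ-like, 0–74) and delusional-ideation (PDI-like,
0–21) questionnaires.

The generator plants a single latent disorganization trait θ ~ N(0, 1) per
participant that drives

* topic drift — each sentence abandons the prompt's topic with probability
  ``drift_intercept + drift_slope·θ`` (lowers the on-topic score),
* immediate word repetition — injected with probability
  ``repeat_intercept + repeat_slope·θ`` (raises the one-node-loop count),
* the questionnaire outcomes — linear in θ plus noise, rounded and floored
  to the questionnaires' ranges.

The ``automated`` version passes the manual text through a parametric
word-corruption channel (independent per-word substitution/deletion/
insertion at ``asr_error_rate``) plus a separate sentence-punctuation
perturbation, because the sentence-level semantic measures are sensitive to
punctuation while word error metrics ignore it.  Two presets mirror the
transcription-quality regimes reported for online ASR: ``sample1_like``
(word error ≈ 0.21) and ``sample2_like`` (≈ 0.08).

Vocabulary, word vectors and word frequencies are generated jointly: topics
are near-orthogonal unit clusters in embedding space, word probabilities are
Zipf-like, and every word carries a Penn POS tag so the dictionary tagger is
exact on synthetic text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coherence import EmbeddingLexicon
from .transcripts import FilterConfig, Transcript, tokenize

__all__ = [
    "GeneratorConfig",
    "SyntheticLexicon",
    "SyntheticCohort",
    "gen_lexicon",
    "gen_transcript",
    "corrupt_transcript",
    "gen_cohort",
    "write_cohort",
    "sample1_like",
    "sample2_like",
]


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 446
    n_excerpts: int = 8
    words_per_excerpt_mean: float = 120.0
    words_per_excerpt_sd: float = 15.0
    sentence_words_mean: float = 10.0
    sentence_words_sd: float = 3.0
    n_topics: int = 8
    vocab_per_topic: int = 60
    embedding_dim: int = 16
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    drift_intercept: float = 0.15
    drift_slope: float = 0.12
    repeat_intercept: float = 0.01
    repeat_slope: float = 0.02
    filler_rate: float = 0.02
    spq_intercept: float = 7.5
    spq_loading: float = 3.0
    pdi_intercept: float = 4.0
    pdi_loading: float = 1.8
    outcome_noise_sd: float = 3.0
    asr_error_rate: float = 0.21
    sub_del_ins_mix: tuple[float, float, float] = (0.6, 0.25, 0.15)
    punct_error_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drift_intercept", "repeat_intercept", "filler_rate",
                     "asr_error_rate", "punct_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.sub_del_ins_mix) - 1.0) > 1e-9:
            raise ValueError("sub_del_ins_mix must sum to 1")
        if self.n_excerpts < 1:
            raise ValueError("n_excerpts must be >= 1")


def sample1_like(**overrides) -> GeneratorConfig:
    """Preset for the noisier transcription regime (word error ≈ 0.21)."""
    return GeneratorConfig(**{"asr_error_rate": 0.21, "punct_error_rate": 0.05, **overrides})


def sample2_like(**overrides) -> GeneratorConfig:
    """Preset for the cleaner transcription regime (word error ≈ 0.08)."""
    return GeneratorConfig(**{"asr_error_rate": 0.08, "punct_error_rate": 0.02, **overrides})


@dataclass
class SyntheticLexicon:
    """Generated embedding lexicon plus its topic structure and POS tags."""

    lexicon: EmbeddingLexicon
    stimuli: dict[str, str]            # excerpt_id -> stimulus description text
    tags: dict[str, str]               # word -> Penn tag
    topic_words: list[np.ndarray]      # per topic: object array of words
    topic_probs: list[np.ndarray]      # per topic: within-topic sampling probs
    excerpt_topic: dict[str, int]      # excerpt_id -> topic index
    counts: dict[str, int]             # word -> synthetic corpus frequency

    @property
    def all_words(self) -> list[str]:
        return [w for tw in self.topic_words for w in tw.tolist()]


_TAG_CHOICES = np.array(
    ["NN", "VB", "JJ", "RB", "PRP", "PRP$", "JJR", "WDT", "WP", "WRB", "DT", "IN"],
    dtype=object,
)
_TAG_PROBS = np.array([0.45, 0.10, 0.08, 0.05, 0.08, 0.03, 0.03, 0.02, 0.02, 0.02, 0.05, 0.07])


def gen_lexicon(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> SyntheticLexicon:
    """Topic-clustered unit word vectors, Zipf probabilities, stimuli, tags.

    Topic centers are orthonormal, so the embedding dimension must be at
    least the number of topics for clusters to be separable.
    """
    if cfg.embedding_dim < cfg.n_topics:
        raise ValueError(
            f"embedding_dim={cfg.embedding_dim} < n_topics={cfg.n_topics}: "
            "topic clusters cannot be separated"
        )
    rng = rng or np.random.default_rng(cfg.rng_seed)
    d, k, m = cfg.embedding_dim, cfg.n_topics, cfg.vocab_per_topic

    centers, _ = np.linalg.qr(rng.normal(size=(d, k)))
    vectors: dict[str, np.ndarray] = {}
    topic_words: list[np.ndarray] = []
    for t in range(k):
        words = np.array([f"t{t:02d}w{j:02d}" for j in range(m)], dtype=object)
        noise = rng.normal(scale=0.4 / np.sqrt(d), size=(m, d))
        vecs = centers[:, t][None, :] + noise
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        for w, v in zip(words.tolist(), vecs):
            vectors[w] = v
        topic_words.append(words)

    vocab = [w for tw in topic_words for w in tw.tolist()]
    ranks = rng.permutation(len(vocab))
    weights = 1.0 / (ranks + 2.7)
    probs = weights / weights.sum()
    counts = {w: int(round(p * 1e7)) + 1 for w, p in zip(vocab, probs)}
    prob_of = dict(zip(vocab, probs))
    topic_probs = []
    for words in topic_words:
        p = np.array([prob_of[w] for w in words.tolist()])
        topic_probs.append(p / p.sum())

    tags = {w: str(rng.choice(_TAG_CHOICES, p=_TAG_PROBS)) for w in vocab}
    tags["um"] = "UH"

    excerpt_topic = {str(e + 1): e % k for e in range(cfg.n_excerpts)}
    stimuli = {}
    for eid, t in excerpt_topic.items():
        sents = []
        for _ in range(2):
            ws = rng.choice(topic_words[t], size=9, p=topic_probs[t])
            sents.append(" ".join(ws.tolist()) + ".")
        stimuli[eid] = " ".join(sents)

    lexicon = EmbeddingLexicon(vectors=vectors, probs=dict(prob_of), dim=d)
    return SyntheticLexicon(
        lexicon=lexicon,
        stimuli=stimuli,
        tags=tags,
        topic_words=topic_words,
        topic_probs=topic_probs,
        excerpt_topic=excerpt_topic,
        counts=counts,
    )


def _clip01(x: float, hi: float) -> float:
    return min(max(x, 0.0), hi)


def gen_transcript(
    theta: float,
    excerpt_id: str,
    lex: SyntheticLexicon,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    participant_id: str = "",
    filter_cfg: FilterConfig | None = None,
) -> Transcript:
    """One manual-version transcript for a participant with trait ``theta``."""
    drift = _clip01(cfg.drift_intercept + cfg.drift_slope * theta, 0.95)
    repeat = _clip01(cfg.repeat_intercept + cfg.repeat_slope * theta, 0.5)
    stim_topic = lex.excerpt_topic[str(excerpt_id)]
    k = cfg.n_topics

    total = max(20, int(round(rng.normal(cfg.words_per_excerpt_mean, cfg.words_per_excerpt_sd))))
    sentences: list[str] = []
    produced = 0
    prev: str | None = None
    while produced < total:
        length = int(np.clip(round(rng.normal(cfg.sentence_words_mean, cfg.sentence_words_sd)), 4, 18))
        length = min(length, total - produced) if total - produced >= 4 else total - produced
        if length <= 0:
            break
        topic = stim_topic
        if k > 1 and rng.random() < drift:
            topic = int(rng.integers(k - 1))
            if topic >= stim_topic:
                topic += 1
        words = rng.choice(lex.topic_words[topic], size=length, p=lex.topic_probs[topic]).tolist()
        produced += length
        out: list[str] = []
        for w in words:
            # injected repeats are the only source of immediate duplicates,
            # so the one-node-loop count is exactly the planted signal
            while w == prev and len(lex.topic_words[topic]) > 1:
                w = str(rng.choice(lex.topic_words[topic], p=lex.topic_probs[topic]))
            if cfg.filler_rate and prev != "um" and rng.random() < cfg.filler_rate:
                out.append("um")
            out.append(w)
            prev = w
            if repeat and rng.random() < repeat:
                out.append(w)
                produced += 1
        sentences.append(" ".join(out) + ".")
    raw = " ".join(sentences)
    return tokenize(raw, filter_cfg, participant_id=participant_id,
                    excerpt_id=str(excerpt_id), version="manual")


def corrupt_transcript(
    t: Transcript,
    lex: SyntheticLexicon,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    filter_cfg: FilterConfig | None = None,
) -> tuple[Transcript, dict[str, int]]:
    """Automated-version transcript via the parametric recognizer channel.

    Each word is independently corrupted with probability ``asr_error_rate``
    (action drawn from the substitution/deletion/insertion mix; substitutions
    and insertions draw a random vocabulary word).  Sentence punctuation is
    perturbed separately: boundaries are dropped (merging sentences) or
    inserted mid-sentence with probability ``punct_error_rate`` each.
    """
    vocab = lex.all_words
    nv = len(vocab)
    p_sub, p_del, _ = cfg.sub_del_ins_mix
    counts = {"substitutions": 0, "deletions": 0, "insertions": 0, "punctuation": 0}

    new_sentences: list[list[str]] = []
    for sent in t.sentence_tokens:
        out: list[str] = []
        for w in sent:
            if rng.random() < cfg.asr_error_rate:
                u = rng.random()
                if u < p_sub:
                    repl = vocab[int(rng.integers(nv))]
                    while repl == w:
                        repl = vocab[int(rng.integers(nv))]
                    out.append(repl)
                    counts["substitutions"] += 1
                elif u < p_sub + p_del:
                    counts["deletions"] += 1
                else:
                    out.append(w)
                    out.append(vocab[int(rng.integers(nv))])
                    counts["insertions"] += 1
            else:
                out.append(w)
        if out:
            new_sentences.append(out)

    # punctuation channel: merge adjacent sentences / split long ones
    if cfg.punct_error_rate and new_sentences:
        merged: list[list[str]] = [new_sentences[0]]
        for sent in new_sentences[1:]:
            if rng.random() < cfg.punct_error_rate:
                merged[-1] = merged[-1] + sent
                counts["punctuation"] += 1
            else:
                merged.append(sent)
        final: list[list[str]] = []
        for sent in merged:
            if len(sent) >= 8 and rng.random() < cfg.punct_error_rate:
                cut = int(rng.integers(3, len(sent) - 2))
                final.extend([sent[:cut], sent[cut:]])
                counts["punctuation"] += 1
            else:
                final.append(sent)
        new_sentences = final

    if not new_sentences:  # pathological all-deleted excerpt: keep one word
        new_sentences = [[vocab[int(rng.integers(nv))]]]
    raw = " ".join(" ".join(s) + "." for s in new_sentences)
    auto = tokenize(raw, filter_cfg, participant_id=t.participant_id,
                    excerpt_id=t.excerpt_id, version="automated")
    return auto, counts


_EDUCATION_LEVELS = [
    "not_finished_high_school",
    "high_school",
    "professional_training",
    "university_ongoing",
    "university_finished",
    "postgraduate",
]


@dataclass
class SyntheticCohort:
    """Generated transcripts (both versions), outcomes and ground truth."""

    config: GeneratorConfig
    lexicon: SyntheticLexicon
    transcripts: list[Transcript]
    outcomes: pd.DataFrame
    ground_truth: pd.DataFrame        # participant_id, theta
    injected_errors: pd.DataFrame     # per (participant, excerpt) channel counts

    def manifest_frame(self, root: str = "transcripts") -> pd.DataFrame:
        rows = [
            {
                "participant_id": t.participant_id,
                "excerpt_id": t.excerpt_id,
                "version": t.version,
                "path": f"{root}/{t.participant_id}_{t.excerpt_id}_{t.version}.txt",
            }
            for t in self.transcripts
        ]
        return pd.DataFrame(rows)

    def pairs(self) -> list[tuple[Transcript, Transcript]]:
        by_key: dict[tuple[str, str, str], Transcript] = {
            (t.participant_id, t.excerpt_id, t.version): t for t in self.transcripts
        }
        out = []
        for (pid, eid, version), t in by_key.items():
            if version == "manual":
                out.append((t, by_key[(pid, eid, "automated")]))
        return out


def gen_cohort(
    cfg: GeneratorConfig,
    *,
    versions: Sequence[str] = ("manual", "automated"),
    filter_cfg: FilterConfig | None = None,
) -> SyntheticCohort:
    """Generate a full cohort: θ per participant, 8 excerpt pairs each,
    outcome/demographic table, and the per-excerpt injected error counts."""
    rng = np.random.default_rng(cfg.rng_seed)
    lex = gen_lexicon(cfg, rng)

    n = cfg.n_participants
    theta = rng.normal(cfg.theta_mean, cfg.theta_sd, size=n)
    noise_spq = rng.normal(0, cfg.outcome_noise_sd, size=n)
    noise_pdi = rng.normal(0, cfg.outcome_noise_sd, size=n)
    spq = np.clip(np.round(cfg.spq_intercept + cfg.spq_loading * theta + noise_spq), 0, 74)
    pdi = np.clip(np.round(cfg.pdi_intercept + cfg.pdi_loading * theta + noise_pdi), 0, 21)

    age = np.clip(np.round(rng.normal(28.1, 6.3, size=n)), 18, 40).astype(int)
    gender = rng.choice(["female", "male", "other"], size=n, p=[0.65, 0.34, 0.01])
    education = rng.choice(len(_EDUCATION_LEVELS), size=n,
                           p=[0.005, 0.215, 0.05, 0.165, 0.355, 0.21])
    device = rng.choice(["computer", "smartphone", "tablet"], size=n, p=[0.73, 0.26, 0.01])

    pids = [f"P{i + 1:04d}" for i in range(n)]
    outcomes = pd.DataFrame(
        {
            "participant_id": pids,
            "spq": spq.astype(int),
            "pdi": pdi.astype(int),
            "age": age,
            "gender": gender,
            "education": education,
            "device": device,
        }
    )

    transcripts: list[Transcript] = []
    error_rows = []
    for pid, th in zip(pids, theta):
        for e in range(1, cfg.n_excerpts + 1):
            manual = gen_transcript(th, str(e), lex, cfg, rng,
                                    participant_id=pid, filter_cfg=filter_cfg)
            if "manual" in versions:
                transcripts.append(manual)
            if "automated" in versions:
                auto, counts = corrupt_transcript(manual, lex, cfg, rng, filter_cfg=filter_cfg)
                transcripts.append(auto)
                error_rows.append({"participant_id": pid, "excerpt_id": str(e), **counts})

    ground_truth = pd.DataFrame({"participant_id": pids, "theta": theta})
    injected = pd.DataFrame(error_rows)
    return SyntheticCohort(
        config=cfg,
        lexicon=lex,
        transcripts=transcripts,
        outcomes=outcomes,
        ground_truth=ground_truth,
        injected_errors=injected,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write everything an extraction run needs: transcripts, manifest,
    outcomes, ground truth, embeddings (word2vec text), word frequencies,
    stimuli and the tagger lexicon."""
    outdir = Path(outdir)
    (outdir / "transcripts").mkdir(parents=True, exist_ok=True)
    (outdir / "stimuli").mkdir(exist_ok=True)

    manifest = cohort.manifest_frame()
    for t, path in zip(cohort.transcripts, manifest["path"]):
        (outdir / path).write_text(t.raw_text, encoding="utf-8")
    manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort.outcomes.to_csv(outdir / "outcomes.csv", index=False)
    cohort.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    if not cohort.injected_errors.empty:
        cohort.injected_errors.to_csv(outdir / "injected_errors.csv", index=False)

    lex = cohort.lexicon
    with open(outdir / "embeddings.txt", "w", encoding="utf-8") as fh:
        fh.write(f"{lex.lexicon.vocab_size} {lex.lexicon.dim}\n")
        for w, v in lex.lexicon.vectors.items():
            fh.write(w + " " + " ".join(f"{x:.8f}" for x in v) + "\n")
    pd.DataFrame(
        {"word": list(lex.counts), "count": list(lex.counts.values())}
    ).to_csv(outdir / "word_freqs.csv", index=False)

    stim_rows = []
    for eid, text in lex.stimuli.items():
        (outdir / "stimuli" / f"{eid}.txt").write_text(text, encoding="utf-8")
        stim_rows.append({"excerpt_id": eid, "path": f"stimuli/{eid}.txt"})
    pd.DataFrame(stim_rows).to_csv(outdir / "stimuli.csv", index=False)
    pd.DataFrame(
        {"word": list(lex.tags), "tag": list(lex.tags.values())}
    ).to_csv(outdir / "tagger_lexicon.csv", index=False)
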