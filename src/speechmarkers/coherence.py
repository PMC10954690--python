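"""SIF sentence embeddings and semantic-coherence statistics.

Each (stop-word/filler-filtered) sentence is embedded as a smooth-inverse-
frequency weighted average of its word vectors, v = (1/k) Σ a/(a+p(w)) vec(w),
which down-weights frequent words without training.  From the sentence-vector
series the four coherence statistics are computed:

* coherence     — mean cosine similarity between adjacent sentences,
* on_topic      — mean cosine similarity between each sentence and the
                  a-priori stimulus description,
* tangentiality — OLS slope of the sentence-stimulus similarities over the
                  sentence index (how fast speech drifts away from the prompt),
* repetition    — maximum cosine similarity over all sentence pairs.

Sentences whose filtered tokens are all out-of-vocabulary (or cancel to a
zero vector) have no direction and are dropped, not scored as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .transcripts import FilterConfig, Transcript, tokenize

__all__ = [
    "EmbeddingLexicon",
    "SemanticMeasures",
    "SEMANTIC_MEASURES",
    "load_embeddings",
    "load_stimuli",
    "sif_embed",
    "cosine",
    "remove_first_pc",
    "semantic_measures",
]

SEMANTIC_MEASURES = (
    "n_words",
    "n_sentences",
    "mean_words_per_sentence",
    "coherence",
    "tangentiality",
    "on_topic",
    "repetition",
)


@dataclass
class EmbeddingLexicon:
    """Word vectors plus unigram probabilities with SIF weighting.

    ``sif_a`` is the smoothing constant of the weight a/(a+p(w)); the default
    1e-3 is the standard choice.  ``oov_policy`` controls words present in
    the vector table but absent from the frequency table: ``skip`` leaves
    them out of embeddings, ``min_prob`` assigns the smallest observed
    probability (rare-word treatment).
    """

    vectors: dict[str, np.ndarray]
    probs: dict[str, float]
    dim: int
    sif_a: float = 1e-3
    oov_policy: str = "skip"
    _weighted: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.sif_a <= 0:
            raise ValueError("sif_a must be positive")
        if self.oov_policy not in ("skip", "min_prob"):
            raise ValueError(f"unknown oov_policy {self.oov_policy!r}")
        if not self.vectors:
            raise ValueError("empty vocabulary")
        if self.oov_policy == "min_prob" and self.probs:
            floor = min(self.probs.values())
            for w in self.vectors:
                self.probs.setdefault(w, floor)
        # precompute a/(a+p)*vec once; embedding is then a dict-lookup sum
        a = self.sif_a
        for w, v in self.vectors.items():
            p = self.probs.get(w)
            if p is not None:
                self._weighted[w] = (a / (a + p)) * v

    def __contains__(self, word: str) -> bool:
        return word in self._weighted

    @property
    def vocab_size(self) -> int:
        return len(self.vectors)


def load_embeddings(
    path: str | Path,
    freq_path: str | Path,
    *,
    sif_a: float = 1e-3,
    oov_policy: str = "skip",
) -> EmbeddingLexicon:
    """Read a word2vec-text vector file and a ``word,count`` frequency CSV.

    The optional word2vec header line ("vocab_size dim") is detected and
    skipped.  All rows must share one dimension.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2 and all(p.isdigit() for p in parts):
                continue  # header
            word, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
                if dim == 0:
                    raise ValueError(f"line {lineno}: no vector components")
            elif len(values) != dim:
                raise ValueError(
                    f"line {lineno}: expected {dim} components, got {len(values)}"
                )
            vectors[word] = np.asarray(values, dtype=np.float64)
    if not vectors:
        raise ValueError(f"no vectors found in {path}")

    freqs = pd.read_csv(freq_path)
    counts = freqs.set_index(freqs.columns[0])[freqs.columns[1]].astype(float)
    total = counts.sum()
    probs = {str(w): c / total for w, c in counts.items() if c > 0}
    return EmbeddingLexicon(vectors=vectors, probs=probs, dim=dim, sif_a=sif_a, oov_policy=oov_policy)


def load_stimuli(stimuli_manifest: str | Path) -> dict[str, str]:
    """Read the stimulus manifest CSV (``excerpt_id,path``) into id → text."""
    manifest = pd.read_csv(stimuli_manifest, dtype=str)
    root = Path(stimuli_manifest).parent
    out = {}
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        out[row.excerpt_id] = p.read_text(encoding="utf-8")
    return out


def sif_embed(tokens: Sequence[str], lex: EmbeddingLexicon) -> np.ndarray | None:
    """SIF embedding of one filtered token sequence; None if no token is
    in-vocabulary.  A zero vector (exact cancellation) is returned as-is;
    downstream cosine treats it as missing."""
    acc = None
    k = 0
    weighted = lex._weighted
    for tok in tokens:
        v = weighted.get(tok)
        if v is not None:
            acc = v if acc is None else acc + v
            k += 1
    if k == 0:
        return None
    return acc / k


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; NaN when either vector has zero norm (a zero-norm
    vector has no direction — similarity is undefined, never 0)."""
    nu = math.sqrt(float(u @ u))
    nv = math.sqrt(float(v @ v))
    if nu == 0.0 or nv == 0.0:
        return math.nan
    return float(u @ v) / (nu * nv)


def remove_first_pc(matrix: np.ndarray) -> np.ndarray:
    """Remove the common component (first right singular vector) from a
    row-wise sentence-embedding matrix.  Off by default in the measures:
    one-minute excerpts rarely have enough sentences to estimate it stably."""
    if len(matrix) < 2:
        return matrix
    _, _, vt = np.linalg.svd(matrix, full_matrices=False)
    pc = vt[0]
    return matrix - np.outer(matrix @ pc, pc)


@dataclass
class SemanticMeasures:
    n_words: int
    n_sentences: int
    mean_words_per_sentence: float
    coherence: float
    tangentiality: float
    on_topic: float
    repetition: float
    n_dropped_sentences: int

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in SEMANTIC_MEASURES}
        d["n_dropped_sentences"] = self.n_dropped_sentences
        return d


def _ols_slope(y: np.ndarray) -> float:
    """Least-squares slope of y on index 0..m-1."""
    x = np.arange(len(y), dtype=np.float64)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return math.nan
    return float(xc @ (y - y.mean())) / denom

def semantic_measures(
    t: Transcript,
    lex: EmbeddingLexicon,
    stimulus: str,
    *,
    filter_cfg: FilterConfig | None = None,
    remove_pc: bool = False,
) -> SemanticMeasures:
    """The four coherence statistics plus verbosity counts for one excerpt.

    Word and sentence counts use the unfiltered view (verbosity); embeddings
    use the filtered view.  Coherence, tangentiality and repetition require
    >= 2 validly embedded sentences, on_topic >= 1; otherwise NaN.
    """
    filter_cfg = filter_cfg or FilterConfig()
    stim_t = tokenize(stimulus, filter_cfg)
    stim_vec = sif_embed(stim_t.filtered_tokens, lex)
    if stim_vec is None or not np.any(stim_vec):
        raise ValueError("stimulus description does not embed to a usable vector")

    embedded = []
    dropped = 0
    for sent in t.filtered_sentence_tokens:
        v = sif_embed(sent, lex)
        if v is None or not np.any(v):
            dropped += 1
        else:
            embedded.append(v)

    n_words = t.n_words
    n_sentences = t.n_sentences
    mean_wps = n_words / n_sentences

    coherence = tangentiality = repetition = on_topic = math.nan
    if embedded:
        mat = np.vstack(embedded)
        if remove_pc:
            mat = remove_first_pc(mat)
        norms = np.linalg.norm(mat, axis=1)
        ok = norms > 0
        mat, norms = mat[ok], norms[ok]
        dropped += int((~ok).sum())
        if len(mat):
            unit = mat / norms[:, None]
            stim_cos = unit @ (stim_vec / np.linalg.norm(stim_vec))
            on_topic = float(stim_cos.mean())
            if len(mat) >= 2:
                sims = unit @ unit.T
                coherence = float(np.mean(np.diag(sims, k=1)))
                iu = np.triu_indices(len(mat), k=1)
                repetition = float(sims[iu].max())
                tangentiality = _ols_slope(stim_cos)

    return SemanticMeasures(
        n_words=n_words,
        n_sentences=n_sentences,
        mean_words_per_sentence=mean_wps,
        coherence=coherence,
        tangentiality=tangentiality,
        on_topic=on_topic,
        repetition=repetition,
        n_dropped_sentences=dropped,
    )
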