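"""Reference/hypothesis word-alignment metrics and manual-vs-automated
marker agreement.

The alignment is the classical minimum-edit-distance dynamic program with
unit substitution/insertion/deletion costs.  From the counted hits (H),
substitutions (S), deletions (D) and insertions (I):

    WER = (S + D + I) / N_ref
    MER = (S + D + I) / (H + S + D + I)
    WIL = 1 − H² / (N_ref · N_hyp)

Words are compared after the same lowercasing/punctuation stripping as the
tokenizer, so punctuation style never counts as a word error.  Among
equal-cost alignments the backtrace prefers hits, then substitutions, then
deletions — the metric values themselves are tie-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transcripts import Transcript

__all__ = [
    "AlignmentCounts",
    "QualityMetrics",
    "align",
    "quality_metrics",
    "transcript_quality",
    "corpus_quality",
    "marker_agreement",
]


@dataclass(frozen=True)
class AlignmentCounts:
    hits: int
    substitutions: int
    deletions: int
    insertions: int

    def __post_init__(self) -> None:
        if min(self.hits, self.substitutions, self.deletions, self.insertions) < 0:
            raise ValueError("alignment counts must be non-negative")

    @property
    def n_ref(self) -> int:
        return self.hits + self.substitutions + self.deletions

    @property
    def n_hyp(self) -> int:
        return self.hits + self.substitutions + self.insertions

    @property
    def errors(self) -> int:
        return self.substitutions + self.deletions + self.insertions

    def __add__(self, other: "AlignmentCounts") -> "AlignmentCounts":
        return AlignmentCounts(
            self.hits + other.hits,
            self.substitutions + other.substitutions,
            self.deletions + other.deletions,
            self.insertions + other.insertions,
        )


@dataclass(frozen=True)
class QualityMetrics:
    wer: float
    mer: float
    wil: float

    def as_dict(self) -> dict[str, float]:
        return {"wer": self.wer, "mer": self.mer, "wil": self.wil}


def align(reference: Sequence[str], hypothesis: Sequence[str]) -> AlignmentCounts:
    """Minimum-edit-distance alignment counts between two word sequences.

    Among equal-cost alignments the one with the most hits is chosen
    (lexicographic (cost, −hits) objective, encoded as a single combined
    weight W = K·cost − hits with K larger than any possible hit count).
    This makes H, S, D, I canonical — in particular swapping reference and
    hypothesis exchanges D and I and leaves H, S, and MER unchanged.
    """
    n, m = len(reference), len(hypothesis)
    if n == 0:
        raise ValueError("empty reference: word error metrics are undefined")
    if m == 0:
        return AlignmentCounts(hits=0, substitutions=0, deletions=n, insertions=0)

    # integer-code the hypothesis once for fast row-wise mismatch vectors
    codes: dict[str, int] = {}
    hyp = np.array([codes.setdefault(w, len(codes)) for w in hypothesis], dtype=np.int64)
    k = n + m + 1  # cost weight dominating any hit count
    idx_k = np.arange(m + 1, dtype=np.int64) * k

    d = np.empty((n + 1, m + 1), dtype=np.int64)
    d[0] = idx_k
    for i in range(1, n + 1):
        ref_code = codes.get(reference[i - 1], -1)
        prev = d[i - 1]
        diag = prev[:-1] + np.where(hyp == ref_code, -1, k)
        cand = np.minimum(diag, prev[1:] + k)
        # row[j] = min over t<=j of cand_full[t] + (j-t)*k: prefix-min trick
        full = np.concatenate(([prev[0] + k], cand))
        d[i] = np.minimum.accumulate(full - idx_k) + idx_k

    h = s = dele = ins = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and reference[i - 1] == hypothesis[j - 1] and d[i, j] == d[i - 1, j - 1] - 1:
            h += 1
            i -= 1
            j -= 1
        elif i > 0 and j > 0 and d[i, j] == d[i - 1, j - 1] + k:
            s += 1
            i -= 1
            j -= 1
        elif i > 0 and d[i, j] == d[i - 1, j] + k:
            dele += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return AlignmentCounts(hits=h, substitutions=s, deletions=dele, insertions=ins)


def quality_metrics(c: AlignmentCounts) -> QualityMetrics:
    """WER, MER and WIL from alignment counts (WIL = 1 when the hypothesis
    is empty: all word information is lost)."""
    wer = c.errors / c.n_ref
    mer = c.errors / (c.hits + c.errors)
    wil = 1.0 if c.n_hyp == 0 else 1.0 - c.hits**2 / (c.n_ref * c.n_hyp)
    return QualityMetrics(wer=wer, mer=mer, wil=wil)


def transcript_quality(reference: Transcript, hypothesis: Transcript) -> QualityMetrics:
    return quality_metrics(align(reference.tokens, hypothesis.tokens))


def corpus_quality(
    pairs: Iterable[tuple[Transcript, Transcript]],
) -> tuple[pd.DataFrame, pd.DataFrame, QualityMetrics]:
    """Quality metrics for a corpus of (manual, automated) transcript pairs.

    Returns (per-excerpt table, per-participant macro-averages, corpus-level
    micro-average pooling counts before dividing).
    """
    rows = []
    pooled = AlignmentCounts(0, 0, 0, 0)
    for ref, hyp in pairs:
        counts = align(ref.tokens, hyp.tokens)
        pooled = pooled + counts
        rows.append(
            {
                "participant_id": ref.participant_id,
                "excerpt_id": ref.excerpt_id,
                **quality_metrics(counts).as_dict(),
            }
        )
    if not rows:
        raise ValueError("no transcript pairs supplied")
    per_excerpt = pd.DataFrame(rows)
    per_participant = (
        per_excerpt.groupby("participant_id", as_index=False)[["wer", "mer", "wil"]].mean()
    )
    return per_excerpt, per_participant, quality_metrics(pooled)


def marker_agreement(features: pd.DataFrame, markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Spearman correlation of participant-level marker means between
    transcript versions.

    ``features`` is the tidy (participant_id, version) × marker table.
    Constant columns get NaN rho.  Requires both versions for >= 3
    participants.
    """
    wide = features.pivot(index="participant_id", columns="version")
    if markers is None:
        markers = [c for c in features.columns if c not in ("participant_id", "version")]
    rows = []
    for marker in markers:
        try:
            man = wide[(marker, "manual")]
            auto = wide[(marker, "automated")]
        except KeyError as exc:
            raise ValueError(f"marker {marker!r} lacks one of the versions") from exc
        ok = man.notna() & auto.notna()
        if ok.sum() < 3:
            raise ValueError(f"marker {marker!r}: need >= 3 complete participant pairs")
        x, y = man[ok].to_numpy(), auto[ok].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, y)
        rows.append({"marker": marker, "rho": rho, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)
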