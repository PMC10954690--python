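"""Transcript reading, tokenization and tidy feature-table I/O.

A *transcript* is the text of one ~1-minute prompt-elicited speech excerpt of
one participant, in one of two versions: ``manual`` (human-corrected) or
``automated`` (speech-recognizer output).  Sentence segmentation trusts the
punctuation present in the text — for automated transcripts that means the
recognizer's punctuation is taken as-is, because the sentence-level semantic
measures are deliberately sensitive to it.

Stop-word / filler filtering is applied only where the semantic-coherence
measures consume tokens; the word-graph and part-of-speech features always
operate on the unfiltered token stream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

__all__ = [
    "STOP_WORDS",
    "FILLER_WORDS",
    "FilterConfig",
    "Transcript",
    "CorpusManifest",
    "EmptyTranscriptError",
    "ValidationError",
    "tokenize",
    "detokenize",
    "load_corpus",
    "read_transcripts",
    "write_manifest",
    "write_features",
    "read_features",
]

#: Small packaged English stop-word list (function words only).  Overridable
#: per :class:`FilterConfig`; the exact list is a configuration choice.
STOP_WORDS = frozenset(
    """a an the and or but if then than that this these those there here
    i you he she it we they me him her us them my your his its our their
    am is are was were be been being do does did have has had having
    of in on at by for with to from as into onto about over under up down
    out off so not no nor very just also too can could will would shall
    should may might must what which who whom when where why how""".split()
)

#: Disfluency fillers removed before semantic embedding ("um" and kin).
FILLER_WORDS = frozenset({"um", "uh", "uhm", "er", "erm", "hmm", "mmm", "mm", "ah", "eh"})

_SENTENCE_RE = re.compile(r"[^.!?]*[.!?]+|[^.!?]+$")
_EDGE_PUNCT_RE = re.compile(r"^[^\w']+|[^\w']+$")
_ALNUM_RE = re.compile(r"[a-z0-9]")


class EmptyTranscriptError(ValueError):
    """Raised when a text contains no alphabetic tokens."""


class ValidationError(ValueError):
    """Raised when a corpus manifest violates its integrity constraints."""


@dataclass(frozen=True)
class FilterConfig:
    """Token-filtering configuration for the semantic-coherence path.

    Removing the same set twice is a no-op (set difference is idempotent),
    so overlapping ``stop_words`` and ``fillers`` are harmless.
    """

    stop_words: frozenset[str] = STOP_WORDS
    fillers: frozenset[str] = FILLER_WORDS
    lowercase: bool = True
    strip_punctuation: bool = True

    @property
    def removed(self) -> frozenset[str]:
        return self.stop_words | self.fillers


def _clean_token(chunk: str) -> str:
    """Strip edge punctuation (keeping internal apostrophes), lowercase."""
    tok = _EDGE_PUNCT_RE.sub("", chunk)
    tok = tok.strip("'_")
    return tok


def _sentence_tokens(sentence: str) -> tuple[list[str], list[str]]:
    """Return (lowercased tokens, original-case tokens) for one sentence."""
    low: list[str] = []
    cased: list[str] = []
    for chunk in re.split(r"[\s‐‑-]+", sentence):
        tok = _clean_token(chunk)
        if tok and _ALNUM_RE.search(tok.lower()):
            cased.append(tok)
            low.append(tok.lower())
    return low, cased


@dataclass
class Transcript:
    """Tokenized, sentence-segmented text of one excerpt/version.

    ``sentence_tokens`` concatenated equals ``tokens`` (unfiltered view);
    ``filtered_sentence_tokens`` is the stop-word/filler-free view used by
    the semantic measures.
    """

    participant_id: str
    excerpt_id: str
    version: str
    raw_text: str
    sentences: list[str]
    sentence_tokens: list[list[str]]
    sentence_tokens_cased: list[list[str]]
    filtered_sentence_tokens: list[list[str]]

    def __post_init__(self) -> None:
        if self.version not in ("manual", "automated"):
            raise ValueError(f"version must be 'manual' or 'automated', got {self.version!r}")

    @property
    def tokens(self) -> list[str]:
        return [t for sent in self.sentence_tokens for t in sent]

    @property
    def filtered_tokens(self) -> list[str]:
        return [t for sent in self.filtered_sentence_tokens for t in sent]

    @property
    def n_words(self) -> int:
        return sum(len(s) for s in self.sentence_tokens)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


def tokenize(
    raw_text: str,
    cfg: FilterConfig | None = None,
    *,
    participant_id: str = "",
    excerpt_id: str = "",
    version: str = "manual",
) -> Transcript:
    """Sentence-segment and tokenize ``raw_text``.

    Sentences split on terminal punctuation (``.!?``); tokens are lowercased
    with edge punctuation stripped; hyphenated words split on the hyphen and
    apostrophe contractions stay single tokens.  Raises
    :class:`EmptyTranscriptError` if no alphabetic token survives.
    """
    cfg = cfg or FilterConfig()
    if not raw_text.strip():
        raise EmptyTranscriptError("transcript text is empty")

    sentences: list[str] = []
    sent_tokens: list[list[str]] = []
    sent_cased: list[list[str]] = []
    for match in _SENTENCE_RE.finditer(raw_text):
        sent = match.group(0).strip()
        if not sent:
            continue
        low, cased = _sentence_tokens(sent)
        if low:
            sentences.append(sent)
            sent_tokens.append(low)
            sent_cased.append(cased)
    if not sent_tokens:
        raise EmptyTranscriptError(f"no alphabetic tokens in {raw_text[:40]!r}")

    removed = cfg.removed
    filtered = [[t for t in sent if t not in removed] for sent in sent_tokens]
    return Transcript(
        participant_id=participant_id,
        excerpt_id=excerpt_id,
        version=version,
        raw_text=raw_text,
        sentences=sentences,
        sentence_tokens=sent_tokens,
        sentence_tokens_cased=sent_cased,
        filtered_sentence_tokens=filtered,
    )


def detokenize(t: Transcript) -> str:
    """Canonical text form of a transcript: one period-terminated sentence
    per token list.  ``tokenize`` is idempotent on this output."""
    return " ".join(" ".join(sent) + "." for sent in t.sentence_tokens)


@dataclass
class CorpusManifest:
    """Rows of (participant_id, excerpt_id, version, path) plus the
    participant-level outcome table (SPQ, PDI, demographics)."""

    transcripts: pd.DataFrame
    outcomes: pd.DataFrame
    root: Path = field(default_factory=Path)

    KEY = ["participant_id", "excerpt_id", "version"]

    def __post_init__(self) -> None:
        dup = self.transcripts.duplicated(subset=self.KEY, keep=False)
        if dup.any():
            bad = self.transcripts.loc[dup, self.KEY].iloc[0].tolist()
            raise ValidationError(f"duplicate manifest row for key {tuple(bad)}")
        known = set(self.outcomes["participant_id"])
        missing = sorted(set(self.transcripts["participant_id"]) - known)
        if missing:
            raise ValidationError(
                "participants missing from the outcome table: " + ", ".join(missing)
            )

    def counts_by_version(self) -> dict[str, int]:
        return self.transcripts["version"].value_counts().to_dict()


def load_corpus(manifest_path: str | Path, outcomes_path: str | Path) -> CorpusManifest:
    """Load and validate a corpus manifest + outcome table (both CSV)."""
    manifest_path = Path(manifest_path)
    transcripts = pd.read_csv(manifest_path, dtype=str)
    required = {"participant_id", "excerpt_id", "version", "path"}
    if not required.issubset(transcripts.columns):
        raise ValidationError(f"manifest must have columns {sorted(required)}")
    bad_version = ~transcripts["version"].isin(["manual", "automated"])
    if bad_version.any():
        raise ValidationError(
            f"unknown version value {transcripts.loc[bad_version, 'version'].iloc[0]!r}"
        )
    outcomes = pd.read_csv(outcomes_path)
    outcomes["participant_id"] = outcomes["participant_id"].astype(str)
    return CorpusManifest(transcripts=transcripts, outcomes=outcomes, root=manifest_path.parent)


def read_transcripts(manifest: CorpusManifest, cfg: FilterConfig | None = None) -> list[Transcript]:
    """Read every transcript file referenced by the manifest."""
    out: list[Transcript] = []
    for row in manifest.transcripts.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest.root / path
        out.append(
            tokenize(
                path.read_text(encoding="utf-8"),
                cfg,
                participant_id=row.participant_id,
                excerpt_id=row.excerpt_id,
                version=row.version,
            )
        )
    return out


def write_manifest(manifest: CorpusManifest, manifest_path: str | Path, outcomes_path: str | Path) -> None:
    manifest.transcripts.to_csv(manifest_path, index=False)
    manifest.outcomes.to_csv(outcomes_path, index=False)


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy (participant, version) × marker table as CSV.

    Column order is preserved so that a write → read round trip is lossless.
    """
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    table.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
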