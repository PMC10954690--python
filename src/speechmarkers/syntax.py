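"""Part-of-speech tag frequencies (Penn Treebank tagset).

The tagger backend is pluggable: anything with a ``tag_sentence(tokens) ->
tags`` method of equal length works.  Two backends ship here — a
deterministic :class:`LexiconTagger` (word → tag dictionary with a default),
and :class:`EnglishRuleTagger`, a small closed-class-lexicon + suffix-rule
tagger for plain English text.  The marker set follows the psychosis-speech
literature: comparative adjectives (JJR), personal (PRP) and possessive
(PRP$) pronouns, WH-determiners (WDT), WH-pronouns (WP), WH-adverbs (WRB),
and the total tag count as a verbosity measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

from .transcripts import Transcript

__all__ = [
    "SYNTACTIC_MEASURES",
    "Tagger",
    "LexiconTagger",
    "EnglishRuleTagger",
    "TaggerContractError",
    "SyntacticMeasures",
    "tag",
    "tag_frequencies",
]

SYNTACTIC_MEASURES = (
    "all_tags",
    "comparative_adjectives",
    "possessive_pronouns",
    "personal_pronouns",
    "wh_determiners",
    "wh_pronouns",
    "wh_adverbs",
)

_TAG_TO_MEASURE = {
    "JJR": "comparative_adjectives",
    "PRP$": "possessive_pronouns",
    "PRP": "personal_pronouns",
    "WDT": "wh_determiners",
    "WP": "wh_pronouns",
    "WRB": "wh_adverbs",
}


class TaggerContractError(RuntimeError):
    """Tagger returned a tag list of the wrong length."""


class Tagger(Protocol):
    def tag_sentence(self, tokens: Sequence[str]) -> list[str]: ...


class LexiconTagger:
    """Deterministic dictionary tagger: word → tag, with a default tag."""

    def __init__(self, lexicon: dict[str, str], default: str = "NN") -> None:
        self.lexicon = {w.lower(): t for w, t in lexicon.items()}
        self.default = default

    def tag_sentence(self, tokens: Sequence[str]) -> list[str]:
        lex = self.lexicon
        return [lex.get(t.lower(), self.default) for t in tokens]


# Closed-class English words; open classes fall back to suffix rules.
_CLOSED_CLASS = {
    **dict.fromkeys(["the", "a", "an", "this", "that", "these", "those",
                     "each", "every", "some", "any", "no", "all", "both"], "DT"),
    **dict.fromkeys(["i", "you", "he", "she", "it", "we", "they", "me", "him",
                     "her", "us", "them", "myself", "yourself", "himself",
                     "herself", "itself", "ourselves", "themselves"], "PRP"),
    **dict.fromkeys(["my", "your", "his", "its", "our", "their", "mine",
                     "yours", "hers", "ours", "theirs"], "PRP$"),
    **dict.fromkeys(["which", "whatever", "whichever"], "WDT"),
    **dict.fromkeys(["who", "whom", "what", "whoever"], "WP"),
    "whose": "WP$",
    **dict.fromkeys(["when", "where", "why", "how", "whenever", "wherever"], "WRB"),
    **dict.fromkeys(["in", "on", "at", "by", "for", "with", "from", "to",
                     "of", "under", "over", "into", "onto", "about", "through",
                     "between", "during", "against", "after", "before",
                     "above", "below", "near", "behind"], "IN"),
    **dict.fromkeys(["and", "or", "but", "nor", "so", "yet"], "CC"),
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "am": "VBP",
    "be": "VB", "been": "VBN", "being": "VBG",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD",
    "not": "RB", "n't": "RB", "very": "RB", "too": "RB", "also": "RB",
    "can": "MD", "could": "MD", "will": "MD", "would": "MD", "shall": "MD",
    "should": "MD", "may": "MD", "might": "MD", "must": "MD",
    "um": "UH", "uh": "UH", "er": "UH", "erm": "UH", "hmm": "UH", "oh": "UH",
    "there": "EX",
    "better": "JJR", "worse": "JJR", "more": "JJR", "less": "JJR",
    "bigger": "JJR", "smaller": "JJR", "larger": "JJR", "older": "JJR",
    "younger": "JJR", "closer": "JJR", "higher": "JJR", "lower": "JJR",
}


class EnglishRuleTagger:
    """Small deterministic tagger: closed-class lexicon plus suffix rules.

    Adequate for the closed-class categories these markers count (pronouns
    and WH-words are closed classes) — open-class words default to noun/verb
    guesses by suffix.
    """

    def __init__(self, extra_lexicon: dict[str, str] | None = None) -> None:
        self.lexicon = dict(_CLOSED_CLASS)
        if extra_lexicon:
            self.lexicon.update({w.lower(): t for w, t in extra_lexicon.items()})

    def tag_sentence(self, tokens: Sequence[str]) -> list[str]:
        tags = []
        for tok in tokens:
            low = tok.lower()
            t = self.lexicon.get(low)
            if t is None:
                if low.endswith("ing"):
                    t = "VBG"
                elif low.endswith("ed"):
                    t = "VBD"
                elif low.endswith("ly"):
                    t = "RB"
                elif low.endswith("est") and len(low) > 4:
                    t = "JJS"
                elif low.isdigit():
                    t = "CD"
                elif low.endswith("s") and len(low) > 3:
                    t = "NNS"
                else:
                    t = "NN"
            tags.append(t)
        return tags


def tag(t: Transcript, tagger: Tagger | None = None) -> list[tuple[str, str]]:
    """Tag every (unfiltered, original-case) token of a transcript.

    Results are keyed to the lowercased tokens.  Raises
    :class:`TaggerContractError` on a length-mismatched backend and
    ``ValueError`` on an empty transcript.
    """
    tagger = tagger or EnglishRuleTagger()
    pairs: list[tuple[str, str]] = []
    any_tokens = False
    for low, cased in zip(t.sentence_tokens, t.sentence_tokens_cased):
        if not cased:
            continue
        any_tokens = True
        tags = tagger.tag_sentence(cased)
        if len(tags) != len(cased):
            raise TaggerContractError(
                f"tagger returned {len(tags)} tags for {len(cased)} tokens"
            )
        pairs.extend(zip(low, tags))
    if not any_tokens:
        raise ValueError("cannot tag a transcript with no tokens")
    return pairs


@dataclass
class SyntacticMeasures:
    all_tags: int
    comparative_adjectives: int
    possessive_pronouns: int
    personal_pronouns: int
    wh_determiners: int
    wh_pronouns: int
    wh_adverbs: int

    def as_dict(self, rates: bool = False) -> dict[str, float]:
        d = {name: getattr(self, name) for name in SYNTACTIC_MEASURES}
        if rates:
            n = self.all_tags
            for name in SYNTACTIC_MEASURES[1:]:
                d[name + "_rate"] = getattr(self, name) / n
        return d


def tag_frequencies(tagged: Sequence[tuple[str, str]]) -> SyntacticMeasures:
    """Raw counts of the six marker categories plus the total tag count."""
    if not tagged:
        raise ValueError("empty tag sequence")
    counts = dict.fromkeys(_TAG_TO_MEASURE.values(), 0)
    for _, t in tagged:
        key = _TAG_TO_MEASURE.get(t)
        if key is not None:
            counts[key] += 1
    return SyntacticMeasures(all_tags=len(tagged), **counts)
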