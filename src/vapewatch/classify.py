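"""Lexicon-based labelling of quit-vaping mentions.

A tweet counts as a quit mention when any surface variant of a cessation
lemma (default ``quit``/``stop``) appears among its tokens.  No co-occurring
vaping term is required — the corpus is already e-cigarette-filtered, and
quit mentions frequently name the product some other way ("quit smokin the
juul").  Negation ("can't quit") is deliberately not handled, matching the
surveillance method this reproduces.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mining import tokenize
from .models import Tweet
from .preprocess import _PUNCT_TABLE

_VOWELS = set("aeiou")


def _inflect(lemma: str) -> set[str]:
    """Surface forms from a fixed suffix table: -s, -ing, -ed.

    Regular English spelling rules only: final-e dropping (vape -> vaping)
    and final-consonant doubling after a consonant-vowel-consonant ending
    (quit -> quitting, stop -> stopped).
    """
    forms = {lemma, lemma + "s"}
    if lemma.endswith("e") and len(lemma) > 1:
        stem = lemma[:-1]
        forms |= {stem + "ing", stem + "ed"}
    elif (
        len(lemma) >= 3
        and lemma[-1] not in _VOWELS | {"w", "x", "y"}
        and lemma[-2] in _VOWELS
        # CVC ending; a "u" that belongs to a "qu" onset counts as consonant
        and (lemma[-3] not in _VOWELS or (lemma[-3] == "u" and lemma[-4:-3] == "q"))
    ):
        forms |= {lemma + lemma[-1] + "ing", lemma + lemma[-1] + "ed"}
    else:
        forms |= {lemma + "ing", lemma + "ed"}
    return forms


def expand_variants(lemmas: Iterable[str]) -> frozenset[str]:
    """Expanded token set for a list of lowercase lemmas.

    ``["quit"]`` yields ``{quit, quits, quitting, quitted}`` and ``["stop"]``
    yields ``{stop, stops, stopping, stopped}``.
    """
    out: set[str] = set()
    for lemma in lemmas:
        out |= _inflect(lemma)
    return frozenset(out)


@dataclass(frozen=True)
class QuitLexicon:
    lemmas: tuple[str, ...]
    variants: frozenset[str]

    def __post_init__(self) -> None:
        if not set(self.lemmas) <= self.variants:
            raise ValueError("lemmas must be contained in their variant set")

    @classmethod
    def from_lemmas(cls, lemmas: Iterable[str]) -> "QuitLexicon":
        lemmas = tuple(w.lower() for w in lemmas)
        return cls(lemmas, expand_variants(lemmas))


DEFAULT_LEXICON = QuitLexicon.from_lemmas(["quit", "stop"])


def classify_quit(
    tweet: Tweet | str, lexicon: QuitLexicon = DEFAULT_LEXICON, stopwords: Iterable[str] = ()
) -> bool:
    """True iff the tweet's token set intersects the lexicon's variants."""
    text = tweet.text if isinstance(tweet, Tweet) else tweet
    return not tokenize(text, stopwords).isdisjoint(lexicon.variants)


def _variant_pattern(lexicon: QuitLexicon, stopwords: Iterable[str]) -> re.Pattern[str]:
    # a variant listed as a stopword can never survive tokenisation
    variants = sorted(lexicon.variants - set(stopwords))
    return re.compile(r"(?<![0-9a-z])(?:%s)(?![0-9a-z])" % "|".join(map(re.escape, variants)))


def label_corpus(
    tweets: Sequence[Tweet],
    lexicon: QuitLexicon = DEFAULT_LEXICON,
    stopwords: Iterable[str] = (),
) -> tuple[list[bool], tuple[int, int]]:
    """Per-tweet quit labels plus (n_total, n_quit).

    Uses a compiled alternation over the punctuation-normalised text; for
    purely alphanumeric variants this is exactly token membership, but runs
    in a single pass per tweet.
    """
    if not tweets:
        return [], (0, 0)
    if not lexicon.variants - set(stopwords):
        return [False] * len(tweets), (len(tweets), 0)
    pattern = _variant_pattern(lexicon, stopwords)
    labels = [pattern.search(t.text.lower().translate(_PUNCT_TABLE)) is not None for t in tweets]
    return labels, (len(labels), sum(labels))
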