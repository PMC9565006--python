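"""Corpus filtering: topical relevance, US geolocation, commercial removal,
and assignment of tweets to the three policy windows.

All keyword matching is case-insensitive on punctuation-normalised text.
Word terms match whole tokens (so promo term ``deal`` does not fire inside
``dealer`` — ``dealer`` is its own term), multi-word terms match consecutive
token phrases (``free shipping``), and the symbol terms ``$`` and ``%`` match
as raw substrings.  Every filter is a pure per-tweet predicate, so filters
are idempotent and their composition is order-independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Sequence

from .models import PeriodWindow, Tweet

#: characters replaced by a space before tokenisation (ASCII punctuation plus
#: the common unicode quotes/dashes seen in tweets)
_PUNCTUATION = r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~""" + "‘’“”–—…"
_PUNCT_TABLE = str.maketrans({ch: " " for ch in _PUNCTUATION})

#: terms matched as raw substrings rather than tokens/phrases
SUBSTRING_TERMS = frozenset({"$", "%"})


def normalize_tokens(text: str) -> list[str]:
    """Lowercase, substitute punctuation with spaces, split on whitespace."""
    return text.lower().translate(_PUNCT_TABLE).split()


@dataclass(frozen=True)
class KeywordSet:
    """A compiled keyword list with per-term matching mode."""

    terms: tuple[str, ...]
    substring_terms: frozenset[str]
    token_terms: frozenset[str]
    phrase_terms: tuple[tuple[str, ...], ...]

    @classmethod
    def compile(cls, terms: Iterable[str]) -> "KeywordSet":
        terms = tuple(t.lower() for t in terms)
        if not terms:
            raise ValueError("keyword set must be non-empty")
        substrings: set[str] = set()
        tokens: set[str] = set()
        phrases: list[tuple[str, ...]] = []
        for term in terms:
            if term in SUBSTRING_TERMS:
                substrings.add(term)
                continue
            parts = tuple(normalize_tokens(term))
            if not parts:
                raise ValueError(f"keyword {term!r} normalises to nothing")
            if len(parts) == 1:
                tokens.add(parts[0])
            else:
                phrases.append(parts)
        return cls(terms, frozenset(substrings), frozenset(tokens), tuple(phrases))


def matches_keywords(text: str, keywords: KeywordSet) -> bool:
    """True iff the text contains any term of the set under its match mode."""
    if not text:
        return False
    lowered = text.lower()
    if any(s in lowered for s in keywords.substring_terms):
        return True
    toks = lowered.translate(_PUNCT_TABLE).split()
    if keywords.token_terms and not keywords.token_terms.isdisjoint(toks):
        return True
    for phrase in keywords.phrase_terms:
        k = len(phrase)
        for i in range(len(toks) - k + 1):
            if tuple(toks[i : i + k]) == phrase:
                return True
    return False


def filter_relevant(tweets: Sequence[Tweet], ecig_keywords: KeywordSet) -> list[Tweet]:
    """Keep only tweets matching an e-cigarette keyword.

    Streamed corpora were collected on these keywords already, but arbitrary
    JSONL inputs are re-screened here so they behave like the collected
    stream.
    """
    return [t for t in tweets if matches_keywords(t.text, ecig_keywords)]


def filter_commercial(
    tweets: Sequence[Tweet], promo_keywords: KeywordSet
) -> tuple[list[Tweet], int]:
    """Drop promotional posts; returns (kept tweets in order, removed count)."""
    kept = [t for t in tweets if not matches_keywords(t.text, promo_keywords)]
    return kept, len(tweets) - len(kept)


def filter_us(tweets: Sequence[Tweet]) -> list[Tweet]:
    """Keep tweets geolocated to the United States.

    A missing country code is treated as not-US: only positively identified
    US tweets enter the study.
    """
    return [t for t in tweets if t.country_code == "US"]


def assign_period(created_at: datetime, windows: Sequence[PeriodWindow]) -> str | None:
    """Map a timestamp to its policy window label, or None if excluded.

    The UTC calendar date is compared against each window, inclusive on both
    ends.  Dates outside all windows (notably Aug–Dec 2019) are excluded.
    """
    day = created_at.astimezone(timezone.utc).date() if created_at.tzinfo else created_at.date()
    for window in windows:
        if window.contains(day):
            return window.label
    return None


def assign_periods(tweets: Sequence[Tweet], windows: Sequence[PeriodWindow]) -> list[str | None]:
    return [assign_period(t.created_at, windows) for t in tweets]
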