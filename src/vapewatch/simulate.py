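"""Seeded generator of Twitter-like corpora with ground truth.

The generator emulates the statistical structure the analysis assumes — a
keyword-collected e-cigarette stream over three policy windows — not real
language.  Every tweet text contains at least one e-cigarette keyword;
quit-labelled tweets embed a surface variant of a cessation lemma;
commercial tweets embed a promotion keyword; all remaining filler comes from
a template vocabulary screened to contain no cessation or promotion term, so
text labels and ground truth agree by construction.

Defaults encode the observed study conditions at one tenth of the original
corpus: per-period quit-mention rates 0.11% / 0.20% / 0.24%, a 10.24%
demographic-inferability rate, and per-period user counts and tweets-per-user
means matching the reported denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .models import DEFAULT_WINDOWS, DemographicRecord, PeriodWindow, Tweet

_PERIOD_KINDS = ("plain", "quit", "commercial")

#: filler vocabulary — deliberately free of cessation variants, promotion
#: terms (including the words of the phrase terms), and symbols
_FILLERS = (
    "today week ago finally really morning night again still miss craving cravings "
    "lungs breathing better feeling good bad day month year first last time trying "
    "tried habit nicotine buzz head rush flavor flavors mango mint coffee friend "
    "friends honestly literally actually maybe never always since after proud happy "
    "hard easy cold turkey officially wish glad sick tired clean air deep breath "
    "money health doctor told kids school work home car walk run gym"
).split()

_ECIG_KEYWORDS = (
    "e-cig e-cigs ecig ecigs electroniccigarette vape vapers vaping vapes e-liquid "
    "ejuice eliquid e-juice vapercon vapeon vapefam vapenation juul"
).split()

_QUIT_VARIANTS = ("quit", "quits", "quitting", "quitted", "stop", "stops", "stopped", "stopping")

#: out-of-lexicon cessation phrasings for the recall negative control
_QUIT_SYNONYMS = ("ditching", "done with", "giving up", "dropping")

_PROMO_SNIPPETS = ("sale", "discount", "promo code", "free shipping", "20% off", "$5 deal")

_NON_US = ("GB", "CA", "AU", "DE", "FR", "MX")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``users_per_period`` and the companion per-period tuples follow the
    window order (pre-announcement, between, post-implementation).
    """

    users_per_period: tuple[int, int, int] = (12674, 4837, 18969)
    tweets_per_user: tuple[float, float, float] = (1.31, 3.50, 3.65)
    quit_rates: tuple[float, float, float] = (0.0011, 0.0020, 0.0024)
    commercial_fraction: float = 0.10
    non_us_fraction: float = 0.25
    female_fraction: float = 0.40
    young_fraction: float = 0.85
    demographics_inferable_rate: float = 0.1024
    synonym_fraction: float = 0.0  # quit tweets phrased outside the lexicon
    seed: int = 0
    windows: tuple[PeriodWindow, ...] = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        if len(self.users_per_period) != len(self.windows):
            raise ValueError("one user count per window is required")
        if all(n == 0 for n in self.users_per_period):
            raise ValueError("at least one period must have users")
        if any(n < 0 for n in self.users_per_period):
            raise ValueError("user counts must be non-negative")
        if any(m < 1.0 for m in self.tweets_per_user):
            raise ValueError("tweets-per-user means must be >= 1")
        for name in ("quit_rates",):
            if any(not 0.0 <= r <= 1.0 for r in getattr(self, name)):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("commercial_fraction", "non_us_fraction", "female_fraction",
                     "young_fraction", "demographics_inferable_rate", "synonym_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("users_per_period", "tweets_per_user", "quit_rates"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("commercial_fraction", "non_us_fraction", "female_fraction",
                    "young_fraction", "demographics_inferable_rate", "synonym_fraction"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """True labels behind a generated corpus.

    ``tweets`` has one row per tweet (tweet_id, user_id, period, is_quit,
    is_commercial, is_us); ``users`` one row per account (user_id, period,
    age, gender, inferable, country_code).
    """

    tweets: pd.DataFrame
    users: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Tweet-level table with user attributes joined, for a single CSV."""
        return self.tweets.merge(
            self.users[["user_id", "age", "gender", "inferable"]], on="user_id", how="left"
        )


def _ztp_lambda(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    if mean <= 1.0 + 1e-9:
        return 0.0
    return float(brentq(lambda lam: lam / -np.expm1(-lam) - mean, 1e-9, 10.0 * mean))


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws (all-ones when the rate is degenerate)."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    if lam == 0.0:
        return np.ones(size, dtype=np.int64)
    out = rng.poisson(lam, size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, int(zero.sum()))
        zero = out == 0
    return out


def render_text(kind: str, rng: np.random.Generator) -> str:
    """One synthetic tweet text of the given kind (plain/quit/commercial).

    Every text carries an e-cigarette keyword; quit texts add a cessation
    variant and commercial texts a promotion snippet.  Length 3–40 tokens.
    """
    if kind not in _PERIOD_KINDS:
        raise ValueError(f"unknown text kind {kind!r}")
    n_filler = int(rng.integers(2, 11))
    tokens = [_FILLERS[i] for i in rng.integers(0, len(_FILLERS), n_filler)]
    tokens.insert(int(rng.integers(0, len(tokens) + 1)), _ECIG_KEYWORDS[int(rng.integers(0, len(_ECIG_KEYWORDS)))])
    if kind == "quit":
        tokens.insert(int(rng.integers(0, len(tokens) + 1)), _QUIT_VARIANTS[int(rng.integers(0, len(_QUIT_VARIANTS)))])
    elif kind == "commercial":
        tokens.insert(int(rng.integers(0, len(tokens) + 1)), _PROMO_SNIPPETS[int(rng.integers(0, len(_PROMO_SNIPPETS)))])
    return " ".join(tokens)


def _render_batch(kinds: np.ndarray, synonym: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Vectorised text rendering for a whole period (kinds: 0/1/2 codes)."""
    n = len(kinds)
    if n == 0:
        return []
    lengths = rng.integers(2, 11, n)
    filler_idx = rng.integers(0, len(_FILLERS), (n, 10))
    kw_idx = rng.integers(0, len(_ECIG_KEYWORDS), n)
    extra_idx = rng.integers(0, max(len(_QUIT_VARIANTS), len(_PROMO_SNIPPETS)), n)
    positions = rng.random((n, 2))
    texts: list[str] = []
    for i in range(n):
        tokens = [_FILLERS[j] for j in filler_idx[i, : lengths[i]]]
        tokens.insert(int(positions[i, 0] * (len(tokens) + 1)), _ECIG_KEYWORDS[kw_idx[i]])
        kind = kinds[i]
        if kind == 1:
            pool = _QUIT_SYNONYMS if synonym[i] else _QUIT_VARIANTS
            tokens.insert(int(positions[i, 1] * (len(tokens) + 1)), pool[extra_idx[i] % len(pool)])
        elif kind == 2:
            tokens.insert(
                int(positions[i, 1] * (len(tokens) + 1)),
                _PROMO_SNIPPETS[extra_idx[i] % len(_PROMO_SNIPPETS)],
            )
        texts.append(" ".join(tokens))
    return texts


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Tweet], list[DemographicRecord], GroundTruth]:
    """Generate one corpus: tweets, demographics table, and ground truth.

    Deterministic given ``config.seed``.  Country is a user-level attribute;
    quit status is assigned per tweet (never to commercial tweets), so the
    configured per-period rates hold among relevant non-commercial tweets
    regardless of the geographic mix.
    """
    rng = np.random.default_rng(config.seed)
    tweets: list[Tweet] = []
    demographics: list[DemographicRecord] = []
    gt_tweets: list[pd.DataFrame] = []
    gt_users: list[pd.DataFrame] = []
    # snowflake-style ids: seed-dependent strictly increasing integers
    next_id = int(rng.integers(10**15, 9 * 10**15))

    for p, window in enumerate(config.windows):
        n_users = config.users_per_period[p]
        if n_users == 0:
            continue
        user_ids = np.array([f"{window.label}_u{k:07d}" for k in range(n_users)])
        is_us = rng.random(n_users) >= config.non_us_fraction
        country = np.where(is_us, "US", rng.choice(_NON_US, n_users))
        age_young = rng.random(n_users) < config.young_fraction
        ages = np.where(
            age_young, rng.integers(18, 35, n_users), rng.integers(35, 71, n_users)
        )
        female = rng.random(n_users) < config.female_fraction
        inferable = rng.random(n_users) < config.demographics_inferable_rate

        lam = _ztp_lambda(config.tweets_per_user[p])
        counts = _sample_ztp(rng, lam, n_users)
        n_tweets = int(counts.sum())
        tweet_user = np.repeat(np.arange(n_users), counts)

        start = int(datetime.combine(window.start, datetime.min.time(), timezone.utc).timestamp())
        end = int(datetime.combine(window.end, datetime.max.time(), timezone.utc).timestamp())
        stamps = np.sort(rng.integers(start, end + 1, n_tweets))

        is_commercial = rng.random(n_tweets) < config.commercial_fraction
        is_quit = (~is_commercial) & (rng.random(n_tweets) < config.quit_rates[p])
        synonym = is_quit & (rng.random(n_tweets) < config.synonym_fraction)
        kinds = np.where(is_commercial, 2, np.where(is_quit, 1, 0))
        texts = _render_batch(kinds, synonym, rng)

        increments = rng.integers(1, 1000, n_tweets)
        ids = next_id + np.cumsum(increments)
        next_id = int(ids[-1]) if n_tweets else next_id

        for i in range(n_tweets):
            u = tweet_user[i]
            tweets.append(
                Tweet(
                    tweet_id=str(ids[i]),
                    user_id=str(user_ids[u]),
                    created_at=datetime.fromtimestamp(int(stamps[i]), timezone.utc),
                    text=texts[i],
                    country_code=str(country[u]),
                    has_profile_face=bool(inferable[u]),
                )
            )
        for k in np.flatnonzero(inferable):
            demographics.append(
                DemographicRecord(
                    str(user_ids[k]), int(ages[k]), "female" if female[k] else "male", True
                )
            )
        gt_tweets.append(
            pd.DataFrame(
                {
                    "tweet_id": ids.astype(str),
                    "user_id": user_ids[tweet_user],
                    "period": window.label,
                    "is_quit": is_quit,
                    "is_commercial": is_commercial,
                    "is_us": is_us[tweet_user],
                }
            )
        )
        gt_users.append(
            pd.DataFrame(
                {
                    "user_id": user_ids,
                    "period": window.label,
                    "age": ages,
                    "gender": np.where(female, "female", "male"),
                    "inferable": inferable,
                    "country_code": country,
                }
            )
        )

    truth = GroundTruth(
        pd.concat(gt_tweets, ignore_index=True), pd.concat(gt_users, ignore_index=True)
    )
    return tweets, demographics, truth
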