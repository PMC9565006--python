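"""Domain types and file I/O for the quit-vaping infoveillance corpus.

The corpus format is a minimal line-delimited JSON dialect mirroring the
fields of a Twitter streaming-API record that the analysis actually uses:

    {"tweet_id": "...", "user_id": "...", "created_at": "...",
     "text": "...", "country_code": "US", "has_profile_face": true}

``country_code`` and ``has_profile_face`` are optional.  Timestamps are
accepted either as ISO-8601 or in the classic Twitter dialect
(``Wed Jan 15 00:00:00 +0000 2020``) and are canonicalised to UTC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PERIOD_LABELS = ("pre_announcement", "between", "post_implementation")

#: classic Twitter streaming-API timestamp, e.g. "Wed Jan 15 00:00:00 +0000 2020"
_TWITTER_TIME_FORMAT = "%a %b %d %H:%M:%S %z %Y"


class CorpusFormatError(ValueError):
    """Raised when an input file is unreadable or mostly malformed."""


def parse_timestamp(value: str) -> datetime:
    """Parse an ISO-8601 or classic-Twitter timestamp to an aware UTC datetime.

    Naive timestamps are taken to be UTC.
    """
    text = value.strip()
    try:
        ts = datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError:
        ts = datetime.strptime(text, _TWITTER_TIME_FORMAT)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def format_timestamp(ts: datetime) -> str:
    """Canonical ISO-8601/UTC rendering used when writing corpora."""
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S+00:00")


@dataclass(frozen=True, slots=True)
class Tweet:
    """One post: the minimal record the pipeline consumes."""

    tweet_id: str
    user_id: str
    created_at: datetime
    text: str
    country_code: str | None = None
    has_profile_face: bool | None = None


@dataclass(frozen=True, slots=True)
class PeriodWindow:
    """A closed calendar-date window (UTC, inclusive on both ends)."""

    label: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window {self.label!r}: start {self.start} > end {self.end}")

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end


#: The three study windows around the FDA cartridge-flavor enforcement policy
#: (announced 2 Jan 2020, implemented 6 Feb 2020).  Aug–Dec 2019 is deliberately
#: left out of every window: state-level flavor bans in that stretch would
#: confound the federal-policy signal.
DEFAULT_WINDOWS: tuple[PeriodWindow, PeriodWindow, PeriodWindow] = (
    PeriodWindow("pre_announcement", date(2019, 6, 13), date(2019, 7, 31)),
    PeriodWindow("between", date(2020, 1, 2), date(2020, 2, 5)),
    PeriodWindow("post_implementation", date(2020, 2, 6), date(2020, 10, 12)),
)


@dataclass(frozen=True, slots=True)
class DemographicRecord:
    """Per-user inferred demographics (stand-in for a face-recognition stage).

    ``face_valid`` is True when exactly one face was detected in the profile
    image; only valid records enter demographic breakdowns.
    """

    user_id: str
    age: int
    gender: str
    face_valid: bool

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age for user {self.user_id!r}")
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")


@dataclass(frozen=True, slots=True)
class PeriodCounts:
    """Per-window tallies of tweets, unique users, and quit mentions."""

    period: str
    n_tweets: int
    n_quit_tweets: int
    n_users: int
    n_quit_users: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_quit_tweets <= self.n_tweets):
            raise ValueError("need 0 <= n_quit_tweets <= n_tweets")
        if not (0 <= self.n_quit_users <= self.n_users):
            raise ValueError("need 0 <= n_quit_users <= n_users")
        if self.n_quit_users > self.n_quit_tweets:
            raise ValueError("n_quit_users cannot exceed n_quit_tweets")


@dataclass
class StudyConfig:
    """All analysis knobs: keyword lists, mining thresholds, windows, bins."""

    ecig_keywords: list[str]
    promo_keywords: list[str]
    stopwords: list[str]
    quit_lemmas: list[str] = field(default_factory=lambda: ["quit", "stop"])
    min_support: int = 1000
    min_rule_probability: float = 0.30
    alpha: float = 0.05
    windows: tuple[PeriodWindow, ...] = DEFAULT_WINDOWS
    age_split: int = 35

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0.0 <= self.min_rule_probability <= 1.0:
            raise ValueError("min_rule_probability must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if len(self.windows) != 3:
            raise ValueError("exactly three period windows are required")
        self.ecig_keywords = [k.lower() for k in self.ecig_keywords]
        self.promo_keywords = [k.lower() for k in self.promo_keywords]
        self.stopwords = [w.lower() for w in self.stopwords]
        self.quit_lemmas = [w.lower() for w in self.quit_lemmas]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        windows = []
        for label in PERIOD_LABELS:
            spec = raw["windows"][label]
            windows.append(PeriodWindow(label, _as_date(spec["start"]), _as_date(spec["end"])))
        return cls(
            ecig_keywords=list(raw["ecig_keywords"]),
            promo_keywords=list(raw["promo_keywords"]),
            stopwords=list(raw["stopwords"]),
            quit_lemmas=list(raw.get("quit_lemmas", ["quit", "stop"])),
            min_support=int(raw.get("min_support", 1000)),
            min_rule_probability=float(raw.get("min_rule_probability", 0.30)),
            alpha=float(raw.get("alpha", 0.05)),
            windows=tuple(windows),
            age_split=int(raw.get("age_split", 35)),
        )

    @classmethod
    def default(cls) -> "StudyConfig":
        """Load the configuration shipped with the package."""
        from importlib.resources import files

        raw = yaml.safe_load(files("vapewatch.data").joinpath("default_config.yaml").read_text())
        return cls.from_dict(raw)


def _as_date(value) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


# ---------------------------------------------------------------------------
# corpus JSONL


def read_tweets_jsonl(path: str | Path) -> list[Tweet]:
    """Read a JSONL corpus, skipping (and counting) malformed lines.

    Raises :class:`CorpusFormatError` if the file cannot be read or if more
    than half of the non-empty lines are malformed — that strongly suggests
    the wrong file was supplied rather than a few bad records.  Duplicate
    ``tweet_id`` lines beyond the first are dropped with a warning.
    """
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise CorpusFormatError(f"cannot read corpus file {path}: {exc}") from exc

    tweets: list[Tweet] = []
    seen_ids: set[str] = set()
    n_lines = 0
    n_bad = 0
    n_dup = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        n_lines += 1
        try:
            obj = json.loads(line)
            tweet = Tweet(
                tweet_id=str(obj["tweet_id"]),
                user_id=str(obj["user_id"]),
                created_at=parse_timestamp(obj["created_at"]),
                text=str(obj["text"]),
                country_code=obj.get("country_code"),
                has_profile_face=obj.get("has_profile_face"),
            )
            if not tweet.tweet_id:
                raise ValueError("empty tweet_id")
        except (KeyError, ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping malformed line %d of %s: %s", lineno, path, exc)
            continue
        if tweet.tweet_id in seen_ids:
            n_dup += 1
            logger.warning("dropping duplicate tweet_id %r at line %d", tweet.tweet_id, lineno)
            continue
        seen_ids.add(tweet.tweet_id)
        tweets.append(tweet)

    if n_lines and n_bad * 2 > n_lines:
        raise CorpusFormatError(
            f"{n_bad}/{n_lines} lines of {path} are malformed; this does not look like a corpus"
        )
    if n_bad or n_dup:
        logger.warning("read %s: %d tweets, %d malformed lines skipped, %d duplicates dropped",
                       path, len(tweets), n_bad, n_dup)
    return tweets


def write_tweets_jsonl(tweets: Iterable[Tweet], path: str | Path) -> None:
    """Write a corpus in the canonical JSONL dialect (read∘write identity)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in tweets:
            obj = {
                "tweet_id": t.tweet_id,
                "user_id": t.user_id,
                "created_at": format_timestamp(t.created_at),
                "text": t.text,
            }
            if t.country_code is not None:
                obj["country_code"] = t.country_code
            if t.has_profile_face is not None:
                obj["has_profile_face"] = t.has_profile_face
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# CSV result tables

_COUNT_COLUMNS = ["period", "n_tweets", "n_quit_tweets", "n_users", "n_quit_users"]


def write_counts_csv(counts: Sequence[PeriodCounts], path: str | Path) -> None:
    if not counts:
        raise ValueError("counts must be non-empty")
    frame = pd.DataFrame([asdict(c) for c in counts], columns=_COUNT_COLUMNS)
    frame.to_csv(path, index=False)


def read_counts_csv(path: str | Path) -> list[PeriodCounts]:
    frame = pd.read_csv(path)
    missing = [c for c in _COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise CorpusFormatError(f"counts table {path} is missing column(s): {', '.join(missing)}")
    return [
        PeriodCounts(row.period, int(row.n_tweets), int(row.n_quit_tweets),
                     int(row.n_users), int(row.n_quit_users))
        for row in frame.itertuples(index=False)
    ]


_DEMOGRAPHIC_COLUMNS = ["user_id", "age", "gender", "face_valid"]

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_demographics_table(path: str | Path) -> list[DemographicRecord]:
    """Read the per-user demographics CSV (deepFace-style output).

    Rows with ``face_valid`` false are retained but flagged; downstream
    breakdowns use only valid rows.  On duplicate ``user_id`` the first row
    wins and a warning is logged.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _DEMOGRAPHIC_COLUMNS if c not in frame.columns]
    if missing:
        raise CorpusFormatError(
            f"demographics table {path} is missing column(s): {', '.join(missing)}"
        )
    records: list[DemographicRecord] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        uid = str(row.user_id)
        if uid in seen:
            logger.warning("duplicate user_id %r in %s; keeping first row", uid, path)
            continue
        seen.add(uid)
        records.append(
            DemographicRecord(uid, int(row.age), str(row.gender).lower(), _parse_bool(row.face_valid))
        )
    return records


def write_demographics_csv(records: Iterable[DemographicRecord], path: str | Path) -> None:
    frame = pd.DataFrame([asdict(r) for r in records], columns=_DEMOGRAPHIC_COLUMNS)
    frame.to_csv(path, index=False)
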