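"""Per-period tallies, two-proportion z-tests, and demographic breakdowns.

Proportions are compared with the pooled two-proportion z-test

    z = (p2 - p1) / sqrt( p̂ (1 - p̂) (1/n1 + 1/n2) ),   p̂ = (x1 + x2)/(n1 + n2)

with a two-sided p-value from the standard normal.  Percentages are rounded
half-up to two decimals, the convention used when reporting prevalence to a
hundredth of a percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from .models import DemographicRecord, PeriodCounts, PeriodWindow, Tweet

logger = logging.getLogger(__name__)

__all__ = [
    "PeriodCounts",
    "ProportionComparison",
    "DemographicBreakdown",
    "tabulate",
    "quit_user_sets",
    "proportion_pct",
    "two_proportion_ztest",
    "demographic_breakdown",
    "pairwise_period_tests",
]


@dataclass(frozen=True, slots=True)
class ProportionComparison:
    """One pooled z-test between two binomial proportions."""

    label1: str
    label2: str
    x1: int
    n1: int
    x2: int
    n2: int
    z: float
    p_value: float
    significant: bool

    @property
    def p1(self) -> float:
        return self.x1 / self.n1

    @property
    def p2(self) -> float:
        return self.x2 / self.n2


@dataclass(frozen=True, slots=True)
class DemographicBreakdown:
    """Gender/age composition of quit-mentioning users in one period.

    Percentages are None when no user in the period could be inferred.
    """

    period: str
    n_inferred: int
    n_female: int
    n_young: int
    female_pct: float | None
    young_pct: float | None


def proportion_pct(x: int, n: int) -> float:
    """100*x/n rounded half-up to two decimals; errors on n == 0."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    return float((Decimal(100 * x) / Decimal(n)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def two_proportion_ztest(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("group1", "group2"),
) -> ProportionComparison:
    """Pooled two-proportion z-test, two-sided.

    Degenerate pooled variance (all successes or all failures) yields z = 0,
    p = 1 with a warning: the data carry no evidence of a difference.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        logger.warning("degenerate pooled variance (x1+x2 in {0, n1+n2}); reporting z=0, p=1")
        z, p = 0.0, 1.0
    else:
        z = (x2 / n2 - x1 / n1) / math.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
    return ProportionComparison(labels[0], labels[1], x1, n1, x2, n2, z, p, p < alpha)


def tabulate(
    tweets: Sequence[Tweet],
    labels: Sequence[bool],
    periods: Sequence[str | None],
    windows: Sequence[PeriodWindow],
) -> list[PeriodCounts]:
    """Per-window totals: tweets, quit tweets, unique users, quit users.

    Users are deduplicated within each window independently — an account
    active in two windows contributes to both denominators.  A quit user has
    at least one quit-labelled tweet in that window.
    """
    if not (len(tweets) == len(labels) == len(periods)):
        raise ValueError("tweets, labels and periods must be parallel")
    users: dict[str, set[str]] = {w.label: set() for w in windows}
    quit_users = quit_user_sets(tweets, labels, periods, windows)
    n_tweets = {w.label: 0 for w in windows}
    n_quit = {w.label: 0 for w in windows}
    for tweet, is_quit, period in zip(tweets, labels, periods):
        if period is None:
            continue
        n_tweets[period] += 1
        users[period].add(tweet.user_id)
        if is_quit:
            n_quit[period] += 1
    return [
        PeriodCounts(w.label, n_tweets[w.label], n_quit[w.label],
                     len(users[w.label]), len(quit_users[w.label]))
        for w in windows
    ]


def quit_user_sets(
    tweets: Sequence[Tweet],
    labels: Sequence[bool],
    periods: Sequence[str | None],
    windows: Sequence[PeriodWindow],
) -> dict[str, set[str]]:
    """user_ids with >= 1 quit-labelled tweet, per window."""
    out: dict[str, set[str]] = {w.label: set() for w in windows}
    for tweet, is_quit, period in zip(tweets, labels, periods):
        if period is not None and is_quit:
            out[period].add(tweet.user_id)
    return out


def dedup_quit_users_across_periods(
    quit_users: Mapping[str, set[str]], order: Sequence[str]
) -> dict[str, set[str]]:
    """Attribute each quit-mentioning user to their earliest window only.

    Alternative numerator convention for the user-level proportions; the
    within-period denominators are unaffected.
    """
    seen: set[str] = set()
    out: dict[str, set[str]] = {}
    for label in order:
        fresh = set(quit_users[label]) - seen
        out[label] = fresh
        seen |= fresh
    return out


def pairwise_period_tests(
    counts: Sequence[PeriodCounts], level: str = "tweets", alpha: float = 0.05
) -> list[ProportionComparison]:
    """Between-period z-tests at the tweet or user level.

    Pairs involving an empty period are skipped (no test is defined there).
    """
    if level == "tweets":
        xn = [(c.n_quit_tweets, c.n_tweets) for c in counts]
    elif level == "users":
        xn = [(c.n_quit_users, c.n_users) for c in counts]
    else:
        raise ValueError("level must be 'tweets' or 'users'")
    out = []
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            (x1, n1), (x2, n2) = xn[i], xn[j]
            if n1 == 0 or n2 == 0:
                logger.warning("skipping %s vs %s: empty period", counts[i].period, counts[j].period)
                continue
            out.append(
                two_proportion_ztest(
                    x1, n1, x2, n2, alpha=alpha, labels=(counts[i].period, counts[j].period)
                )
            )
    return out


def demographic_breakdown(
    quit_users: Mapping[str, Iterable[str]],
    demographics: Sequence[DemographicRecord],
    age_split: int = 35,
    alpha: float = 0.05,
    order: Sequence[str] | None = None,
) -> tuple[list[DemographicBreakdown], dict[str, list[ProportionComparison]]]:
    """Gender and age composition of quit-mentioning users per period.

    Only records with a valid single-face detection and inferred age >= 18
    are usable.  The young bin is the half-open interval [18, age_split);
    users exactly at the split fall in the older bin.  Returns the per-period
    breakdowns plus pairwise z-tests for the female and young shares.
    """
    usable = {}
    for rec in demographics:
        if rec.face_valid and rec.age >= 18 and rec.user_id not in usable:
            usable[rec.user_id] = rec
    order = list(order) if order is not None else list(quit_users)
    rows: list[DemographicBreakdown] = []
    for period in order:
        inferred = [usable[u] for u in quit_users[period] if u in usable]
        n = len(inferred)
        n_female = sum(r.gender == "female" for r in inferred)
        n_young = sum(18 <= r.age < age_split for r in inferred)
        if n == 0:
            logger.warning("no inferrable quit-mentioning users in period %r", period)
            rows.append(DemographicBreakdown(period, 0, 0, 0, None, None))
        else:
            rows.append(
                DemographicBreakdown(
                    period, n, n_female, n_young,
                    proportion_pct(n_female, n), proportion_pct(n_young, n),
                )
            )
    tests: dict[str, list[ProportionComparison]] = {"female": [], "young": []}
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if a.n_inferred == 0 or b.n_inferred == 0:
                continue
            tests["female"].append(
                two_proportion_ztest(a.n_female, a.n_inferred, b.n_female, b.n_inferred,
                                     alpha=alpha, labels=(a.period, b.period))
            )
            tests["young"].append(
                two_proportion_ztest(a.n_young, a.n_inferred, b.n_young, b.n_inferred,
                                     alpha=alpha, labels=(a.period, b.period))
            )
    return rows, tests
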