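"""End-to-end analysis: filters -> (optional mining) -> classifier -> stats.

This is the library surface behind the command-line ``analyze`` step; tests
and scripts call it directly with in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import classify, mining, preprocess, stats
from .models import DemographicRecord, PeriodCounts, StudyConfig, Tweet

logger = logging.getLogger(__name__)


class EmptyCorpusError(RuntimeError):
    """No relevant tweets survive the filters."""


@dataclass
class AnalysisResult:
    counts: list[PeriodCounts]
    tweet_tests: list[stats.ProportionComparison]
    user_tests: list[stats.ProportionComparison]
    breakdowns: list[stats.DemographicBreakdown]
    demo_tests: dict[str, list[stats.ProportionComparison]]
    labels: list[bool]          # parallel to kept_tweets
    periods: list[str | None]   # parallel to kept_tweets
    kept_tweets: list[Tweet]
    lexicon: classify.QuitLexicon
    stage_counts: dict[str, int] = field(default_factory=dict)


def derive_lexicon(
    tweets: Sequence[Tweet], config: StudyConfig, anchor: str = "vaping"
) -> classify.QuitLexicon:
    """Re-derive the cessation lexicon by frequent itemset mining.

    Mines pair rules against the anchor token at the configured support and
    rule-probability thresholds and expands the selected antecedents through
    the standard suffix table.
    """
    transactions = mining.make_transactions(
        ((t.tweet_id, t.text) for t in tweets), config.stopwords
    )
    itemsets = mining.mine_frequent_itemsets(transactions, config.min_support)
    rules = mining.derive_pair_rules(itemsets)
    lemmas = mining.select_quit_keywords(
        rules, anchor=anchor, min_support=config.min_support,
        min_rule_probability=config.min_rule_probability,
    )
    logger.info("mined lexicon lemmas: %s", lemmas)
    return classify.QuitLexicon.from_lemmas(lemmas) if lemmas else classify.QuitLexicon((), frozenset())


def run_analysis(
    tweets: Sequence[Tweet],
    demographics: Sequence[DemographicRecord],
    config: StudyConfig,
    mine_lexicon: bool = False,
    dedup_users_across_periods: bool = False,
) -> AnalysisResult:
    """Run the full pipeline on an in-memory corpus.

    Raises :class:`EmptyCorpusError` when nothing relevant survives the
    relevance/US/commercial filters.
    """
    ecig = preprocess.KeywordSet.compile(config.ecig_keywords)
    promo = preprocess.KeywordSet.compile(config.promo_keywords)

    n_read = len(tweets)
    relevant = preprocess.filter_relevant(tweets, ecig)
    us = preprocess.filter_us(relevant)
    kept, n_commercial = preprocess.filter_commercial(us, promo)
    logger.info(
        "filters: read=%d relevant=%d us=%d non_commercial=%d",
        n_read, len(relevant), len(us), len(kept),
    )
    if not kept:
        raise EmptyCorpusError("no relevant tweets after filtering")

    periods = preprocess.assign_periods(kept, config.windows)
    n_excluded = sum(p is None for p in periods)

    if mine_lexicon:
        lexicon = derive_lexicon(kept, config)
    else:
        lexicon = classify.QuitLexicon.from_lemmas(config.quit_lemmas)
    labels, (_, n_quit) = classify.label_corpus(kept, lexicon, config.stopwords)

    counts = stats.tabulate(kept, labels, periods, config.windows)
    order = [w.label for w in config.windows]
    quit_users = stats.quit_user_sets(kept, labels, periods, config.windows)
    if dedup_users_across_periods:
        quit_users = stats.dedup_quit_users_across_periods(quit_users, order)
        counts = [
            PeriodCounts(c.period, c.n_tweets, c.n_quit_tweets, c.n_users,
                         len(quit_users[c.period]))
            for c in counts
        ]
    tweet_tests = stats.pairwise_period_tests(counts, "tweets", config.alpha)
    user_tests = stats.pairwise_period_tests(counts, "users", config.alpha)
    breakdowns, demo_tests = stats.demographic_breakdown(
        quit_users, demographics, age_split=config.age_split, alpha=config.alpha, order=order
    )

    stage_counts = {
        "read": n_read,
        "relevant": len(relevant),
        "not_relevant": n_read - len(relevant),
        "us": len(us),
        "non_us": len(relevant) - len(us),
        "kept": len(kept),
        "commercial": n_commercial,
        "excluded_window": n_excluded,
        "labeled": len(labels),
        "quit": n_quit,
    }
    return AnalysisResult(
        counts, tweet_tests, user_tests, breakdowns, demo_tests,
        labels, periods, list(kept), lexicon, stage_counts,
    )
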