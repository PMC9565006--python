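"""Proportions, pooled z-tests, tabulation, and demographic breakdowns."""

import math
from datetime import datetime, timezone

import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from vapewatch import (
    DEFAULT_WINDOWS,
    DemographicRecord,
    Tweet,
    demographic_breakdown,
    pairwise_period_tests,
    proportion_pct,
    tabulate,
    two_proportion_ztest,
)
from vapewatch.stats import dedup_quit_users_across_periods, quit_user_sets


@pytest.mark.parametrize(
    "x,n,expected",
    [
        (1644, 691979, 0.24),
        (0, 100, 0.00),
        (16, 39, 41.03),
        (1, 800, 0.13),  # 0.125 rounds half-up, not to even
        (50, 100, 50.00),
    ],
)
def test_proportion_pct(x, n, expected):
    assert proportion_pct(x, n) == expected


def test_proportion_pct_rejects_bad_input():
    with pytest.raises(ValueError):
        proportion_pct(1, 0)
    with pytest.raises(ValueError):
        proportion_pct(5, 4)


def test_ztest_identical_proportions():
    t = two_proportion_ztest(5, 10, 5, 10)
    assert t.z == 0.0 and t.p_value == 1.0 and not t.significant


def test_ztest_degenerate_pooled_variance():
    t = two_proportion_ztest(0, 10, 0, 20)
    assert t.z == 0.0 and t.p_value == 1.0
    t = two_proportion_ztest(10, 10, 20, 20)
    assert t.z == 0.0 and t.p_value == 1.0


def test_ztest_closed_form_values():
    t = two_proportion_ztest(189, 165782, 1644, 691979)
    assert t.z == pytest.approx(9.79, abs=0.005)
    assert t.p_value < 0.001
    t = two_proportion_ztest(7, 20, 16, 39)
    assert t.z == pytest.approx(0.45, abs=0.005)
    assert t.p_value == pytest.approx(0.65, abs=0.005)
    assert not t.significant


counts_pair = st.tuples(st.integers(1, 500), st.integers(1, 500)).map(
    lambda t: (min(t), max(t))
)


@given(counts_pair, counts_pair)
def test_ztest_symmetry_and_p_consistency(g1, g2):
    """Swapping groups negates z; p always equals 2(1 - Phi(|z|))."""
    (x1, n1), (x2, n2) = g1, g2
    a = two_proportion_ztest(x1, n1, x2, n2)
    b = two_proportion_ztest(x2, n2, x1, n1)
    assert a.z == pytest.approx(-b.z, abs=1e-12)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
    assert a.p_value == pytest.approx(2.0 * norm.sf(abs(a.z)), abs=1e-12)
    assert 0.0 <= a.p_value <= 1.0


@given(counts_pair, counts_pair)
def test_ztest_agrees_with_statsmodels(g1, g2):
    statsmodels = pytest.importorskip("statsmodels.stats.proportion")
    (x1, n1), (x2, n2) = g1, g2
    ours = two_proportion_ztest(x1, n1, x2, n2)
    z_ref, p_ref = statsmodels.proportions_ztest([x2, x1], [n2, n1])
    if not math.isnan(z_ref):
        assert ours.z == pytest.approx(z_ref, abs=1e-10)
        assert ours.p_value == pytest.approx(p_ref, abs=1e-10)


def _tweet(tid, uid, day, text="vaping"):
    return Tweet(tid, uid, datetime(*day, tzinfo=timezone.utc), text, "US")


def test_tabulate_one_user_many_quit_tweets():
    tweets = [_tweet(str(i), "u1", (2020, 1, 15)) for i in range(3)]
    labels = [True, True, True]
    periods = ["between"] * 3
    counts = tabulate(tweets, labels, periods, DEFAULT_WINDOWS)
    between = counts[1]
    assert (between.n_tweets, between.n_quit_tweets) == (3, 3)
    assert (between.n_users, between.n_quit_users) == (1, 1)


def test_tabulate_empty_period_all_zero():
    counts = tabulate([], [], [], DEFAULT_WINDOWS)
    assert all(
        (c.n_tweets, c.n_quit_tweets, c.n_users, c.n_quit_users) == (0, 0, 0, 0)
        for c in counts
    )


FIXTURE = [
    # (tweet_id, user, day, quit?)  -- hand-tallied below
    ("1", "a", (2019, 6, 20), True),
    ("2", "a", (2019, 6, 21), False),
    ("3", "b", (2019, 7, 1), False),
    ("4", "a", (2020, 1, 10), True),
    ("5", "c", (2020, 1, 11), True),
    ("6", "c", (2020, 1, 12), True),
    ("7", "d", (2020, 3, 1), False),
    ("8", "e", (2020, 3, 2), False),
    ("9", "f", (2019, 9, 1), True),  # excluded window
]


def _fixture():
    tweets = [_tweet(tid, uid, day) for tid, uid, day, _ in FIXTURE]
    labels = [q for *_, q in FIXTURE]
    periods = [None if tid == "9" else p for tid, p in zip(
        [f[0] for f in FIXTURE],
        ["pre_announcement"] * 3 + ["between"] * 3 + ["post_implementation"] * 2 + [None],
    )]
    return tweets, labels, periods


def test_tabulate_hand_fixture():
    tweets, labels, periods = _fixture()
    counts = tabulate(tweets, labels, periods, DEFAULT_WINDOWS)
    pre, between, post = counts
    assert (pre.n_tweets, pre.n_quit_tweets, pre.n_users, pre.n_quit_users) == (3, 1, 2, 1)
    assert (between.n_tweets, between.n_quit_tweets, between.n_users, between.n_quit_users) == (3, 3, 2, 2)
    assert (post.n_tweets, post.n_quit_tweets, post.n_users, post.n_quit_users) == (2, 0, 2, 0)


def test_tabulate_permutation_invariant():
    tweets, labels, periods = _fixture()
    base = tabulate(tweets, labels, periods, DEFAULT_WINDOWS)
    order = [5, 2, 7, 0, 8, 1, 6, 3, 4]
    shuffled = tabulate(
        [tweets[i] for i in order], [labels[i] for i in order],
        [periods[i] for i in order], DEFAULT_WINDOWS,
    )
    assert shuffled == base


def test_cross_period_user_dedup():
    tweets, labels, periods = _fixture()
    users = quit_user_sets(tweets, labels, periods, DEFAULT_WINDOWS)
    assert users["pre_announcement"] == {"a"}
    assert users["between"] == {"a", "c"}
    deduped = dedup_quit_users_across_periods(
        users, ["pre_announcement", "between", "post_implementation"]
    )
    assert deduped["between"] == {"c"}  # "a" already counted in the pre window


def test_pairwise_period_tests_cover_all_pairs():
    tweets, labels, periods = _fixture()
    counts = tabulate(tweets, labels, periods, DEFAULT_WINDOWS)
    tests = pairwise_period_tests(counts, "tweets")
    assert [(t.label1, t.label2) for t in tests] == [
        ("pre_announcement", "between"),
        ("pre_announcement", "post_implementation"),
        ("between", "post_implementation"),
    ]
    with pytest.raises(ValueError):
        pairwise_period_tests(counts, "retweets")


def _demo(uid, age, gender, valid=True):
    return DemographicRecord(uid, age, gender, valid)


def test_demographic_breakdown_counts_and_boundaries():
    quit_users = {
        "pre_announcement": {"a", "b", "c", "d"},
        "between": {"e", "f"},
        "post_implementation": set(),
    }
    demographics = [
        _demo("a", 34, "female"),        # young bin [18, 35)
        _demo("b", 35, "male"),          # exactly 35 -> older bin
        _demo("c", 17, "female"),        # under 18 -> excluded entirely
        _demo("d", 50, "female", valid=False),  # invalid face -> excluded
        _demo("e", 20, "male"),
        _demo("f", 70, "female"),
    ]
    rows, tests = demographic_breakdown(quit_users, demographics, age_split=35)
    pre, between, post = rows
    assert (pre.n_inferred, pre.n_female, pre.n_young) == (2, 1, 1)
    assert pre.female_pct == 50.00 and pre.young_pct == 50.00
    assert (between.n_inferred, between.n_female, between.n_young) == (2, 1, 1)
    assert post.n_inferred == 0 and post.female_pct is None and post.young_pct is None
    # degenerate periods are skipped in pairwise testing
    assert len(tests["female"]) == 1 and len(tests["young"]) == 1


def test_demographic_breakdown_printed_percentages():
    quit_users = {"pre_announcement": {f"u{i}" for i in range(20)}}
    demographics = [
        _demo(f"u{i}", 25 if i < 14 else 40, "female" if i < 7 else "male")
        for i in range(20)
    ]
    rows, _ = demographic_breakdown(quit_users, demographics)
    assert rows[0].female_pct == 35.00
    assert rows[0].young_pct == 70.00
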