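"""Hashtag extraction, 2x2 tallies, the one-tailed chi-square, BH selection,
and the composed enrichment screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from taglift.errors import CoverageError, DegenerateTableError
from taglift.hashtag_discovery import (ContingencyTable2x2,
                                       HashtagTestResult, benjamini_hochberg,
                                       bh_select, chi_square_one_sided,
                                       discover, extract_hashtags, tally)
from taglift.text_classifier import Call, ConstantClassifier, PredictionRecord


# ---- extract_hashtags --------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ("no tags here", set()),
    ("#ilovebeer", {"ilovebeer"}),
    ("Try #CraftBeer and #craftbeer! #beer#wine", {"craftbeer", "beer", "wine"}),
    ("ending #", set()),
    ("#UPPER #lower", {"upper", "lower"}),
])
def test_extract_hashtags(text, expected):
    assert extract_hashtags(text) == expected


# ---- tally -------------------------------------------------------------

def _pred(tid, positive):
    return PredictionRecord(tid, 0.9 if positive else 0.1,
                            Call.POSITIVE if positive else Call.NEGATIVE)


def test_tally_direct_enumeration():
    tweets = [
        {"tweet_id": "1", "text": "x #tag"},
        {"tweet_id": "2", "text": "y #tag"},
        {"tweet_id": "3", "text": "z"},
        {"tweet_id": "4", "text": "w"},
    ]
    preds = [_pred("1", True), _pred("2", False), _pred("3", True),
             _pred("4", False)]
    t = tally(tweets, preds, "tag")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_tally_set_semantics_and_conservation():
    tweets = [{"tweet_id": "1", "text": "#tag twice #tag"},
              {"tweet_id": "2", "text": "none"}]
    preds = [_pred("1", True), _pred("2", True)]
    t = tally(tweets, preds, "tag")
    assert t.occurrences == 1  # duplicate inside one tweet counts once
    assert t.n == 2


def test_tally_missing_prediction_raises():
    tweets = [{"tweet_id": "1", "text": "#tag"}]
    with pytest.raises(CoverageError):
        tally(tweets, [], "tag")


# ---- chi_square_one_sided ----------------------------------------------

def test_chi_square_enrichment_example():
    stat, p = chi_square_one_sided(ContingencyTable2x2(8, 2, 2, 8))
    assert stat == pytest.approx(7.2)
    assert p == pytest.approx(0.0036451790457678, rel=1e-9)


def test_chi_square_no_association():
    stat, p = chi_square_one_sided(ContingencyTable2x2(5, 5, 5, 5))
    assert stat == 0.0
    assert p == 0.5


def test_chi_square_depletion_direction():
    _, p = chi_square_one_sided(ContingencyTable2x2(2, 8, 8, 2))
    assert p == pytest.approx(0.9963548209542322, rel=1e-9)


def test_zero_marginal_degenerate():
    with pytest.raises(DegenerateTableError):
        chi_square_one_sided(ContingencyTable2x2(3, 0, 5, 0))


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.tuples(*[st.integers(min_value=1, max_value=40)] * 4))
def test_chi_square_equals_squared_z_and_sides_consistent(cells):
    """chi2 == z^2 for the two-proportion z statistic, and
    2*min(p_one, 1-p_one) == the two-sided chi-square p."""
    a, b, c, d = cells
    table = ContingencyTable2x2(a, b, c, d)
    stat, p_one = chi_square_one_sided(table)
    p1, p2_ = a / (a + b), c / (c + d)
    pooled = (a + c) / (a + b + c + d)
    denom = pooled * (1 - pooled) * (1 / (a + b) + 1 / (c + d))
    z = (p1 - p2_) / np.sqrt(denom) if denom > 0 else 0.0
    assert stat == pytest.approx(z ** 2, rel=1e-9, abs=1e-12)
    p_two = stats.chi2.sf(stat, df=1)
    assert 2 * min(p_one, 1 - p_one) == pytest.approx(p_two, rel=1e-9)


# ---- BH selection ------------------------------------------------------

def _results_from_pvalues(pvals, occurrences=10):
    return [
        HashtagTestResult(f"tag{i}", ContingencyTable2x2(occurrences, 0, 5, 5),
                          1.0, p)
        for i, p in enumerate(pvals)
    ]


def test_bh_hand_worked_example():
    sel, annotated = bh_select(
        _results_from_pvalues([0.01, 0.02, 0.03, 0.04, 0.2]), q=0.05)
    assert sel == {"tag0", "tag1", "tag2", "tag3"}
    thresholds = {r.hashtag: r.p_adjusted_rank_threshold for r in annotated}
    assert thresholds["tag0"] == pytest.approx(0.01)
    assert thresholds["tag4"] == pytest.approx(0.05)


def test_bh_all_null():
    sel, _ = bh_select(_results_from_pvalues([1.0] * 10), q=0.05)
    assert sel == set()


def test_min_count_excludes_before_testing():
    rare = HashtagTestResult("rare", ContingencyTable2x2(4, 0, 5, 5), 1.0, 1e-9)
    common = HashtagTestResult("common", ContingencyTable2x2(9, 1, 5, 5), 1.0, 0.02)
    dull = HashtagTestResult("dull", ContingencyTable2x2(5, 5, 5, 5), 0.0, 0.9)
    sel, annotated = bh_select([rare, common, dull], q=0.05, min_count=5)
    tested = {r.hashtag for r in annotated}
    assert tested == {"common", "dull"}  # 4 occurrences: never tested, m == 2
    assert sel == {"common"}  # 0.02 <= 1 * 0.05 / 2
    assert len(annotated) == 2


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30),
       st.sampled_from([0.01, 0.05, 0.1, 0.25]))
def test_bh_matches_brute_force_and_statsmodels(pvals, q):
    mask = benjamini_hochberg(pvals, q)
    # brute force straight from the step-up definition
    order = np.argsort(pvals, kind="stable")
    m = len(pvals)
    k = 0
    for i in range(1, m + 1):
        if pvals[order[i - 1]] <= i * q / m:
            k = i
    expected = np.zeros(m, dtype=bool)
    if k:
        expected = np.asarray(pvals) <= pvals[order[k - 1]]
    np.testing.assert_array_equal(mask, expected)
    reject_sm, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    np.testing.assert_array_equal(mask, reject_sm)


def test_bh_monotone_in_q():
    rng = np.random.default_rng(1)
    pvals = rng.uniform(size=40)
    prev: set = set()
    for q in (0.01, 0.05, 0.1, 0.2, 0.5):
        sel = {i for i, r in enumerate(benjamini_hochberg(pvals, q)) if r}
        assert prev <= sel
        prev = sel


# ---- discover ----------------------------------------------------------

def test_discover_recovers_planted_hashtags(default_world, trained_model):
    res = discover(default_world.tweets, trained_model)
    planted = set(default_world.truth.planted_hashtags)
    selected = set(res.significant)
    assert len(selected & planted) / len(planted) >= 0.9
    assert len(selected - planted) <= max(1, 0.1 * len(selected))


def test_discover_order_invariant(default_world, trained_model):
    tweets = list(default_world.tweets)
    rng = np.random.default_rng(0)
    shuffled = [tweets[i] for i in rng.permutation(len(tweets))]
    r1 = discover(tweets, trained_model)
    r2 = discover(shuffled, trained_model)
    assert r1.significant == r2.significant
    assert [x.hashtag for x in r1.results] == [x.hashtag for x in r2.results]


def test_discover_constant_classifier_degenerate(default_world):
    """All-positive calls give b=d=0 everywhere: nothing is testable."""
    res = discover(default_world.tweets[:500], ConstantClassifier(0.6))
    assert res.results == []
    assert res.significant == []
    assert res.n_degenerate > 0


def test_discover_drops_tweets_without_hashtags(trained_model):
    tweets = [{"tweet_id": "1", "text": "plain words"},
              {"tweet_id": "2", "text": "#beer yay"}]
    res = discover(tweets, ConstantClassifier(0.5), min_count=1)
    assert res.n_dropped_no_hashtag == 1
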