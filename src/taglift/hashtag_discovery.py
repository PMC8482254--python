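"""Hashtag enrichment testing among classifier-positive posts.

For every hashtag occurring in the corpus, a 2x2 table crosses per-tweet
hashtag presence with the classifier's positive/negative call. A Pearson
chi-square (1 df, no continuity correction) is turned into a one-tailed
"greater" p-value — small only when the hashtag is *enriched* among
positive calls — and hashtags with at least ``min_count`` occurrences are
passed through Benjamini-Hochberg step-up selection at FDR ``q``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import CoverageError, DegenerateTableError
from .text_classifier import Call, predict

logger = logging.getLogger(__name__)

_HASHTAG_RE = re.compile(r"#(\w+)")


def extract_hashtags(text: str) -> set[str]:
    """Case-folded maximal word-character runs after each '#', '#' stripped.

    A tweet contributes each hashtag at most once (set semantics); an
    adjacent '#' starts a new hashtag ("#beer#wine" -> {"beer", "wine"}).
    """
    return set(_HASHTAG_RE.findall(text.casefold()))


def tweet_hashtags(tweet: dict) -> set[str]:
    """A tweet's hashtag set: the explicit field when present, else
    extracted from the text."""
    tags = tweet.get("hashtags")
    if tags is not None:
        return {t.casefold().lstrip("#") for t in tags}
    return extract_hashtags(tweet.get("text", ""))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a: tag & positive, b: tag & negative, c: no tag & positive,
    d: no tag & negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def occurrences(self) -> int:
        """Per-tweet presence count of the hashtag."""
        return self.a + self.b


@dataclass(frozen=True)
class HashtagTestResult:
    hashtag: str
    table: ContingencyTable2x2
    statistic: float
    p_one_sided: float
    p_adjusted_rank_threshold: float = float("nan")
    significant: bool = False


@dataclass
class DiscoveryResult:
    results: list[HashtagTestResult]  # tested hashtags, sorted by (p, tag)
    significant: list[str]
    n_input: int
    n_dropped_no_hashtag: int
    n_below_min_count: int
    n_degenerate: int
    n_positive_calls: int
    n_negative_calls: int


def tally(tweets: list[dict], predictions, hashtag: str) -> ContingencyTable2x2:
    """Cross per-tweet presence of ``hashtag`` with the prediction call.

    ``predictions`` maps tweet_id -> PredictionRecord (or is a list of
    records); every tweet must be covered exactly once.
    """
    if not isinstance(predictions, dict):
        predictions = {r.item_id: r for r in predictions}
    hashtag = hashtag.casefold().lstrip("#")
    a = b = c = d = 0
    for tw in tweets:
        rec = predictions.get(tw["tweet_id"])
        if rec is None:
            raise CoverageError(f"no prediction for tweet {tw['tweet_id']!r}")
        present = hashtag in tweet_hashtags(tw)
        positive = rec.call is Call.POSITIVE
        if present and positive:
            a += 1
        elif present:
            b += 1
        elif positive:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def chi_square_one_sided(table: ContingencyTable2x2,
                         continuity_correction: bool = False
                         ) -> tuple[float, float]:
    """Pearson chi-square with a one-tailed "greater" (enrichment) p-value.

    With 1 degree of freedom the chi-square is the square of the
    two-proportion z statistic, so halving the two-sided p is exact:
    p_one = p_two/2 when the hashtag rate among positive calls exceeds the
    rate among negative calls, else 1 - p_two/2 (a zero statistic gives 0.5).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    marginals = (a + b, c + d, a + c, b + d)
    if min(marginals) == 0:
        raise DegenerateTableError(
            f"zero marginal in table {table}; one-sided p undefined")
    stat, p_two, _, _ = stats.chi2_contingency(
        [[a, b], [c, d]], correction=continuity_correction)
    enriched = a / (a + b) > c / (c + d)
    p_one = p_two / 2.0 if enriched else 1.0 - p_two / 2.0
    return float(stat), float(p_one)


def benjamini_hochberg(pvalues, q: float) -> np.ndarray:
    """BH step-up rejection mask over ``pvalues`` at FDR level ``q``.

    k = max{i : p_(i) <= i*q/m}; reject every hypothesis with p <= p_(k).
    Ties therefore share one all-or-none decision.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) * q) / m  # i*q/m, evaluated as written
    passed = p[order] <= thresholds
    if not passed.any():
        return np.zeros(m, dtype=bool)
    k = int(np.max(np.nonzero(passed)[0]))  # 0-based index of p_(k)
    return p <= p[order][k]


def bh_select(results: list[HashtagTestResult], q: float = 0.05,
              min_count: int = 5) -> tuple[set[str], list[HashtagTestResult]]:
    """Min-count filter, then BH at FDR ``q`` over the remaining hashtags.

    Hashtags with fewer than ``min_count`` occurrences are excluded *before*
    testing, so they do not count toward m. Returns the significant hashtag
    set and the annotated (tested) results.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    eligible = [r for r in results if r.table.occurrences >= min_count]
    if not eligible:
        logger.warning("no hashtags meet the min_count=%d filter", min_count)
        return set(), []
    m = len(eligible)
    pvals = [r.p_one_sided for r in eligible]
    reject = benjamini_hochberg(pvals, q)
    ranks = np.empty(m, dtype=int)
    ranks[np.argsort(pvals, kind="stable")] = np.arange(1, m + 1)
    annotated = [
        replace(r, significant=bool(rej),
                p_adjusted_rank_threshold=float(q * rank / m))
        for r, rej, rank in zip(eligible, reject, ranks)
    ]
    selected = {r.hashtag for r in annotated if r.significant}
    return selected, annotated


def discover(tweets: list[dict], model, q: float = 0.05, min_count: int = 5,
             threshold: float = 0.5,
             continuity_correction: bool = False) -> DiscoveryResult:
    """Full enrichment screen: predict -> tally -> chi-square -> BH.

    Tweets without any hashtag are dropped (count reported), mirroring a
    hashtag-containing analysis corpus. Tables with a zero marginal (e.g.
    when every tweet receives the same call) are degenerate and never
    tested. Results are sorted by p then hashtag.
    """
    tagged = [(tw, tweet_hashtags(tw)) for tw in tweets]
    kept = [(tw, tags) for tw, tags in tagged if tags]
    n_dropped = len(tweets) - len(kept)
    if n_dropped:
        logger.info("dropped %d tweets without hashtags", n_dropped)

    records = predict(model, [tw.get("text", "") for tw, _ in kept],
                      ids=[tw["tweet_id"] for tw, _ in kept],
                      threshold=threshold)
    pos_with: dict[str, int] = {}
    neg_with: dict[str, int] = {}
    n_pos = n_neg = 0
    for (tw, tags), rec in zip(kept, records):
        positive = rec.call is Call.POSITIVE
        if positive:
            n_pos += 1
        else:
            n_neg += 1
        bucket = pos_with if positive else neg_with
        for tag in tags:
            bucket[tag] = bucket.get(tag, 0) + 1

    all_tags = sorted(set(pos_with) | set(neg_with))
    raw: list[HashtagTestResult] = []
    n_degenerate = 0
    n_below = 0
    for tag in all_tags:
        a = pos_with.get(tag, 0)
        b = neg_with.get(tag, 0)
        table = ContingencyTable2x2(a, b, n_pos - a, n_neg - b)
        if table.occurrences < min_count:
            n_below += 1
            continue
        try:
            stat, p_one = chi_square_one_sided(table, continuity_correction)
        except DegenerateTableError:
            n_degenerate += 1
            continue
        raw.append(HashtagTestResult(tag, table, stat, p_one))

    selected, annotated = bh_select(raw, q=q, min_count=min_count)
    annotated.sort(key=lambda r: (r.p_one_sided, r.hashtag))
    return DiscoveryResult(
        results=annotated,
        significant=sorted(selected),
        n_input=len(tweets),
        n_dropped_no_hashtag=n_dropped,
        n_below_min_count=n_below,
        n_degenerate=n_degenerate,
        n_positive_calls=n_pos,
        n_negative_calls=n_neg,
    )


def results_to_json(result: DiscoveryResult) -> list[dict]:
    """JSON-serializable form of the tested hashtags (for hashtags.json)."""
    return [
        {
            "hashtag": r.hashtag,
            "table": {"a": r.table.a, "b": r.table.b,
                      "c": r.table.c, "d": r.table.d},
            "statistic": r.statistic,
            "p_one_sided": r.p_one_sided,
            "p_adjusted_rank_threshold": r.p_adjusted_rank_threshold,
            "significant": r.significant,
        }
        for r in result.results
    ]
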