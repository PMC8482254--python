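"""Spearman/OLS building blocks and the Table-1-shaped suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from taglift.association import (adjusted_regression, results_to_frame,
                                 run_suite, spearman)
from taglift.errors import (CollinearityError, DegenerateInputError,
                            ParameterError)
from taglift.geo_prevalence import CONFOUNDER_FIELDS


def _conf(n, rng=None, collinear_with=None):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(rng.standard_normal((n, len(CONFOUNDER_FIELDS))),
                      columns=list(CONFOUNDER_FIELDS))
    if collinear_with is not None:
        df[CONFOUNDER_FIELDS[0]] = collinear_with
    return df


# ---- spearman ----------------------------------------------------------

def test_perfect_monotone():
    assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)


def test_tied_ranks_hand_oracle():
    rho, _ = spearman([1, 2, 2, 3], [1, 3, 2, 4])
    assert rho == pytest.approx(0.9486832980505138, rel=1e-12)


def test_constant_vector_degenerate():
    with pytest.raises(DegenerateInputError):
        spearman([1, 1, 1], [1, 2, 3])


def test_length_and_nan_guards():
    with pytest.raises(ParameterError):
        spearman([1, 2], [1, 2])
    with pytest.raises(ParameterError):
        spearman([1, 2, np.nan], [1, 2, 3])


def test_spearman_matches_rank_pearson_oracle():
    """Average-rank + Pearson + t-approximation, computed by hand."""
    rng = np.random.default_rng(7)
    from scipy import stats
    for _ in range(200):
        n = int(rng.integers(4, 25))
        x = rng.integers(0, 8, n).astype(float)  # ties likely
        y = rng.integers(0, 8, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        r = np.corrcoef(rx, ry)[0, 1]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(r, rel=1e-9, abs=1e-12)
        if abs(r) < 1:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p_oracle = 2 * stats.t.sf(abs(t), n - 2)
            assert p == pytest.approx(p_oracle, rel=1e-6, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=1_000_000))
def test_spearman_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(15)
    y = rng.standard_normal(15)
    rho, _ = spearman(x, y)
    rho_t, _ = spearman(np.exp(x), y ** 3 + 5 * y)  # strictly increasing maps
    assert rho_t == pytest.approx(rho, rel=1e-9, abs=1e-12)


# ---- adjusted_regression -----------------------------------------------

def test_planted_linear_truth_recovered():
    rng = np.random.default_rng(0)
    n = 200
    prev = rng.uniform(0, 10, n)
    y = 2.0 * prev + 0.001 * rng.standard_normal(n)
    beta, p, diag = adjusted_regression(prev, y, _conf(n, rng))
    assert beta == pytest.approx(2.0, rel=0.01)
    assert p < 1e-10


def test_collinear_design_raises_with_names():
    rng = np.random.default_rng(1)
    n = 50
    prev = rng.uniform(0, 10, n)
    conf = _conf(n, rng, collinear_with=prev)  # confounder duplicates prevalence
    y = rng.standard_normal(n)
    with pytest.raises(CollinearityError) as err:
        adjusted_regression(prev, y, conf)
    assert "prevalence" in err.value.columns or CONFOUNDER_FIELDS[0] in err.value.columns


def test_too_few_areas_rejected():
    with pytest.raises(ParameterError):
        adjusted_regression(np.ones(5), np.ones(5), _conf(5))


def test_beta_invariant_to_confounder_rescaling():
    rng = np.random.default_rng(2)
    n = 120
    prev = rng.uniform(0, 5, n)
    conf = _conf(n, rng)
    y = 1.5 * prev + conf.to_numpy() @ np.arange(1, 8) + rng.standard_normal(n)
    beta1, p1, _ = adjusted_regression(prev, y, conf)
    rescaled = conf * 100.0 + 7.0
    beta2, p2, _ = adjusted_regression(prev, y, rescaled)
    assert beta2 == pytest.approx(beta1, rel=1e-8)
    assert p2 == pytest.approx(p1, rel=1e-6, abs=1e-12)


# ---- run_suite ---------------------------------------------------------

def test_suite_recovers_positive_association(default_world, default_areas):
    planted = set(default_world.truth.planted_hashtags)
    results = run_suite(default_world.tweets, default_areas, {"all": planted})
    by_outcome = {r.outcome_name: r for r in results}
    linked = by_outcome["alcohol_outcome"]
    assert linked.spearman_rho > 0.3 and linked.beta > 0
    assert linked.beta_p < 0.01
    null = by_outcome["independent_outcome"]
    assert abs(null.spearman_rho) < 0.3


def test_suite_row_count_and_category_composition(default_world, default_areas):
    planted = list(default_world.truth.planted_hashtags)
    sets = {"all": set(planted), "first5": set(planted[:5])}
    results = run_suite(default_world.tweets, default_areas, sets)
    assert len(results) == 2 * 2  # 2 categories x 2 outcomes
    frame = results_to_frame(results)
    assert set(frame["category"]) == {"all", "first5"}
    # category run differs from "all" only through the tweet subset: an
    # identical subset gives identical rows
    dup = run_suite(default_world.tweets, default_areas,
                    {"copy": set(planted)})
    all_rows = frame[frame["category"] == "all"].drop(columns="category")
    dup_rows = results_to_frame(dup).drop(columns="category")
    pd.testing.assert_frame_equal(all_rows.reset_index(drop=True),
                                  dup_rows.reset_index(drop=True))


def test_missing_outcome_skipped(default_world, default_areas):
    planted = set(default_world.truth.planted_hashtags)
    results = run_suite(default_world.tweets, default_areas, {"all": planted},
                        outcomes=["absent_outcome", "alcohol_outcome"])
    assert [r.outcome_name for r in results] == ["alcohol_outcome"]
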