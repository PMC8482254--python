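"""Area-level association between hashtag prevalence and outcomes.

Two tracks per outcome, mirroring a crude-then-adjusted ecological design:

* crude: Spearman rank correlation (average ranks for ties, two-sided p via
  the t approximation on n-2 degrees of freedom);
* adjusted: ordinary least squares of the outcome on per-capita prevalence
  plus the seven area confounders and an intercept, reporting the
  prevalence coefficient and its two-sided t-test p.

No correction is applied across outcome rows; each row reports its own n
after inclusion filters and pairwise-complete outcome deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DegenerateInputError, ParameterError
from .geo_prevalence import (CONFOUNDER_FIELDS, DEFAULT_SCALE,
                             DEFAULT_YEAR_RANGE, GeoArea,
                             apply_inclusion_filters, compute_prevalence,
                             filter_alcohol_tweets)

logger = logging.getLogger(__name__)

CONDITION_NUMBER_LIMIT = 1e8


@dataclass(frozen=True)
class AssociationResult:
    outcome_name: str
    level: str
    category: str  # "all" or a hashtag-category label
    n: int
    spearman_rho: float
    spearman_p: float
    beta: float
    beta_p: float


@dataclass
class RegressionDiagnostics:
    condition_number: float
    condition_flag: bool
    params: dict[str, float] = field(default_factory=dict)
    conf_int: tuple[float, float] = (float("nan"), float("nan"))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with average ranks for ties; two-sided p via the
    t-approximation with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ParameterError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ParameterError("missing values must be dropped by the caller")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("rho undefined on a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def adjusted_regression(prevalence, outcome, confounders
                        ) -> tuple[float, float, RegressionDiagnostics]:
    """OLS of outcome on [intercept, prevalence, 7 confounders].

    Returns (beta, two-sided p for beta, diagnostics). A rank-deficient
    design raises CollinearityError naming the dependent columns.
    """
    prevalence = np.asarray(prevalence, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    conf = pd.DataFrame(confounders)
    missing = [c for c in CONFOUNDER_FIELDS if c not in conf.columns]
    if missing:
        raise ParameterError(f"confounder matrix missing columns: {missing}")
    conf = conf.loc[:, list(CONFOUNDER_FIELDS)].astype(float)
    n = len(outcome)
    n_predictors = 1 + len(CONFOUNDER_FIELDS)
    if n <= n_predictors + 1:
        raise ParameterError(
            f"need more than {n_predictors + 1} areas, got {n}")
    X = pd.DataFrame({"prevalence": prevalence}).join(conf.reset_index(drop=True))
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        offenders = _dependent_columns(X)
        raise CollinearityError(offenders)
    fit = sm.OLS(outcome, X).fit()
    cond = float(np.linalg.cond(X.to_numpy()))
    diag = RegressionDiagnostics(
        condition_number=cond,
        condition_flag=cond > CONDITION_NUMBER_LIMIT,
        params={k: float(v) for k, v in fit.params.items()},
        conf_int=tuple(map(float, fit.conf_int().loc["prevalence"])),
    )
    return float(fit.params["prevalence"]), float(fit.pvalues["prevalence"]), diag


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Columns lying in the span of the remaining ones."""
    arr = X.to_numpy()
    full_rank = np.linalg.matrix_rank(arr)
    offenders = []
    for j, name in enumerate(X.columns):
        rest = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(rest) == full_rank:
            offenders.append(str(name))
    return offenders or list(map(str, X.columns))


def run_suite(tweets: list[dict], areas: list[GeoArea],
              hashtag_sets: dict[str, set],
              outcomes: list[str] | None = None,
              year_range=DEFAULT_YEAR_RANGE,
              min_tweets: int = 1, min_population: float = 1000.0,
              scale: float = DEFAULT_SCALE) -> list[AssociationResult]:
    """One association row per (hashtag category, outcome).

    For each named hashtag set ("all" plus any beverage-category subsets),
    prevalence is recomputed on the restricted tweet subset; inclusion
    filters and per-outcome missing-value deletion are then applied before
    the crude and adjusted analyses.
    """
    if outcomes is None:
        names = set()
        for a in areas:
            names.update(a.outcomes)
        outcomes = sorted(names)
    area_by_id = {a.area_id: a for a in areas}
    level = areas[0].level if areas else "unknown"
    results = []
    for category in sorted(hashtag_sets):
        _, geotagged = filter_alcohol_tweets(tweets, hashtag_sets[category])
        report = compute_prevalence(geotagged, areas, year_range, scale)
        records = apply_inclusion_filters(report.records, min_tweets,
                                          min_population)
        for outcome in outcomes:
            rows = [(r, area_by_id[r.area_id]) for r in records
                    if outcome in area_by_id[r.area_id].outcomes]
            if not rows:
                logger.warning("outcome %r absent from all included areas; "
                               "skipped", outcome)
                continue
            prev = np.array([r.per_10k for r, _ in rows])
            y = np.array([a.outcomes[outcome] for _, a in rows])
            conf = pd.DataFrame([a.confounders for _, a in rows])
            rho, rho_p = spearman(prev, y)
            beta, beta_p, _ = adjusted_regression(prev, y, conf)
            results.append(AssociationResult(
                outcome_name=outcome, level=level, category=category,
                n=len(rows), spearman_rho=rho, spearman_p=rho_p,
                beta=beta, beta_p=beta_p))
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular report: one row per (outcome, category)."""
    return pd.DataFrame([
        {"outcome": r.outcome_name, "level": r.level, "category": r.category,
         "n": r.n, "spearman_rho": r.spearman_rho, "spearman_p": r.spearman_p,
         "beta": r.beta, "beta_p": r.beta_p}
        for r in results
    ])
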