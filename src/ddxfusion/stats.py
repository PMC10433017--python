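"""Paired accuracy evaluation of single and combined DDx lists.

The unit of analysis is an *evaluation row*: one (case, replicate,
combination-arm) observation recording whether the confirmed final
diagnosis appears in the index list and in each combined list, plus the
shared-diagnosis (concordance) count and the common/uncommon stratum.
Replicates from the two physicians are treated as independent rows, the
same optimistic convention the study design uses: 103 cases × 2
replicates × 2 other generators gives 412 two-system rows, and × 2
replicates gives 206 three-system rows.

Metrics:

* top-10 inclusion accuracy with exact (Clopper–Pearson) binomial 95% CIs
  — the exact interval reproduces the printed CIs, e.g. 47/103 → 36%–56%;
* McNemar's paired test of index vs combined hits (exact binomial by
  default, continuity-corrected chi-square available);
* univariable logistic regression of index-list accuracy on the shared
  count, reported as an odds ratio per one shared diagnosis with Wald CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import INDEX_GENERATOR, CaseRecord
from .combine import combine_shared, combine_union, combine_weighted_1n, count_shared

__all__ = [
    "COMBINATION_METHODS",
    "AccuracyResult",
    "McNemarResult",
    "LogisticFit",
    "DataError",
    "SeparationError",
    "contains_correct",
    "expand_rows",
    "accuracy_with_ci",
    "mcnemar_paired",
    "fit_logistic_shared",
    "summarize_strata",
]

COMBINATION_METHODS = ("union", "weighted_1n", "shared")


class DataError(ValueError):
    """Raised when a cohort is structurally unfit for expansion."""


class SeparationError(RuntimeError):
    """Raised when the logistic fit is degenerate (perfect separation)."""


@dataclass(frozen=True)
class AccuracyResult:
    """k/n proportion with a two-sided exact binomial confidence interval."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError("numerator cannot exceed denominator")
        if not self.ci_low <= self.proportion <= self.ci_high:
            raise ValueError("CI must bracket the proportion")

    def __str__(self) -> str:
        return (
            f"{self.numerator}/{self.denominator} "
            f"({100 * self.proportion:.0f}%, {100 * self.level:.0f}% CI "
            f"{100 * self.ci_low:.0f}%-{100 * self.ci_high:.0f}%)"
        )


@dataclass(frozen=True)
class McNemarResult:
    """Discordant-pair counts and p-value of the paired McNemar test.

    ``b`` counts pairs where the index list hit and the combined list
    missed; ``c`` the reverse.
    """

    b: int
    c: int
    p_value: float
    variant: str
    statistic: float | None = None


@dataclass(frozen=True)
class LogisticFit:
    """Univariable logistic fit of hit ~ shared_count (Wald inference)."""

    beta0: float
    beta1: float
    se_beta1: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    p_value: float
    n_rows: int
    converged: bool


def contains_correct(list_entries: Iterable[str], truth: str) -> bool:
    """True iff the confirmed diagnosis appears anywhere in the list.

    Membership, not rank, defines the outcome; an empty (e.g. shared-only)
    list always counts as a miss.
    """
    if not truth:
        raise ValueError("truth diagnosis id must be non-empty")
    return truth in set(list_entries)


def expand_rows(cohort: Sequence[CaseRecord]) -> pd.DataFrame:
    """Expand case records into the paired evaluation rows.

    For each record, one row per (index, other-generator) pair — the
    two-system arms — and, when at least two other generators are present,
    one all-generators row (the three-system arm for the study design).
    Each row carries the index hit, the hit of each combined list (union,
    weighted_1n, shared), per-generator single-list hits, the shared count
    of the arm, and the stratum.
    """
    if not cohort:
        raise DataError("cohort is empty")
    all_others: list[str] = []
    for rec in cohort:
        for g in rec.lists:
            if g != INDEX_GENERATOR and g not in all_others:
                all_others.append(g)

    rows: list[dict] = []

    def add_row(rec: CaseRecord, arm: str, others: Sequence[str]) -> None:
        index_list = rec.index_list
        other_lists = [rec.lists[g] for g in others]
        all_lists = [index_list, *other_lists]
        combined_hits = {
            "union": contains_correct(combine_union(all_lists).ids, rec.truth),
            "weighted_1n": contains_correct(
                combine_weighted_1n(all_lists).ids, rec.truth
            ),
            "shared": contains_correct(combine_shared(all_lists).ids, rec.truth),
        }
        row: dict = {
            "case_id": rec.case_id,
            "replicate_id": rec.replicate_id,
            "arm": arm,
            "stratum": rec.stratum,
            "shared_count": count_shared(index_list, other_lists),
            "index_hit": contains_correct(index_list.ids, rec.truth),
        }
        for g in all_others:
            row[f"hit_{g}"] = (
                contains_correct(rec.lists[g].ids, rec.truth) if g in others else pd.NA
            )
        for m in COMBINATION_METHODS:
            row[f"{m}_hit"] = combined_hits[m]
        rows.append(row)

    for rec in cohort:
        others = [g for g in rec.lists if g != INDEX_GENERATOR]
        if not others:
            raise DataError(
                f"case {rec.case_id!r} replicate {rec.replicate_id!r} has no "
                "generator besides the index list"
            )
        for g in others:
            add_row(rec, f"2-system:{g}", [g])
        if len(others) >= 2:
            add_row(rec, f"{len(others) + 1}-system", others)
    return pd.DataFrame(rows)


def accuracy_with_ci(hits: Iterable[bool], level: float = 0.95) -> AccuracyResult:
    """Proportion of hits with a two-sided Clopper–Pearson exact CI.

    The lower bound is exactly 0 when no hits occur and the upper bound
    exactly 1 when all do.
    """
    hits = [bool(h) for h in hits]
    if not hits:
        raise ValueError("accuracy requires at least one observation")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie strictly in (0, 1)")
    k, n = sum(hits), len(hits)
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    return AccuracyResult(k, n, k / n, float(lo), float(hi), level)


def mcnemar_paired(
    index_hits: Sequence[bool],
    combined_hits: Sequence[bool],
    variant: str = "exact",
) -> McNemarResult:
    """McNemar's test on paired index/combined hit indicators.

    ``exact``: two-sided exact binomial test on the discordant pairs,
    p = min(1, 2·P(X ≤ min(b, c))) with X ~ Binomial(b + c, 1/2).
    ``continuity_corrected``: chi-square statistic (|b−c|−1)²/(b+c) on
    1 df.  With no discordant pairs the p-value is 1.
    """
    index_hits = [bool(h) for h in index_hits]
    combined_hits = [bool(h) for h in combined_hits]
    if len(index_hits) != len(combined_hits):
        raise ValueError(
            f"paired samples differ in length: {len(index_hits)} vs {len(combined_hits)}"
        )
    if not index_hits:
        raise ValueError("McNemar test requires at least one pair")
    b = sum(1 for i, c in zip(index_hits, combined_hits) if i and not c)
    c = sum(1 for i, c_ in zip(index_hits, combined_hits) if not i and c_)
    n_disc = b + c
    if variant == "exact":
        if n_disc == 0:
            return McNemarResult(b, c, 1.0, variant)
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n_disc, 0.5)))
        return McNemarResult(b, c, p, variant)
    if variant == "continuity_corrected":
        if n_disc == 0:
            return McNemarResult(b, c, 1.0, variant, statistic=0.0)
        stat = (abs(b - c) - 1) ** 2 / n_disc
        p = float(sps.chi2.sf(stat, df=1))
        return McNemarResult(b, c, p, variant, statistic=stat)
    raise ValueError(f"unknown McNemar variant {variant!r}")


def fit_logistic_shared(
    shared_counts: Sequence[int],
    hits: Sequence[bool],
    level: float = 0.95,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of hit on shared count.

    logit P(hit) = β0 + β1·shared_count, fitted by iteratively reweighted
    least squares with Wald standard errors from the observed information.
    The slope is reported as an odds ratio per one additional shared
    diagnosis.  Degenerate inputs (a single outcome class, a constant
    predictor, perfect separation) raise instead of silently returning a
    divergent fit.
    """
    x = np.asarray(shared_counts, dtype=float)
    y = np.asarray([bool(h) for h in hits], dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("shared_counts and hits must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("logistic fit requires at least two rows")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes (hit and miss) must be present")
    if len(np.unique(x)) < 2:
        raise ValueError("shared_count must take at least two distinct values")
    # perfect separation: the predictor ranges of the two classes do not overlap
    x_hit, x_miss = x[y == 1], x[y == 0]
    if x_miss.max() < x_hit.min() or x_hit.max() < x_miss.min():
        raise SeparationError(
            "complete separation: shared counts of hits and misses do not "
            "overlap; the ML estimate of the slope is infinite"
        )
    design = sm.add_constant(x)
    try:
        res = sm.Logit(y, design).fit(disp=False, maxiter=200)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge")
    beta0, beta1 = res.params
    se1 = float(res.bse[1])
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    return LogisticFit(
        beta0=float(beta0),
        beta1=float(beta1),
        se_beta1=se1,
        odds_ratio=float(np.exp(beta1)),
        or_ci_low=float(np.exp(beta1 - z * se1)),
        or_ci_high=float(np.exp(beta1 + z * se1)),
        p_value=float(res.pvalues[1]),
        n_rows=int(x.size),
        converged=True,
    )


def _stratum_mask(rows: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "total":
        return pd.Series(True, index=rows.index)
    return rows["stratum"] == stratum


def summarize_strata(
    rows: pd.DataFrame,
    level: float = 0.95,
    strata: Sequence[str] = ("total", "common", "uncommon"),
) -> pd.DataFrame:
    """Accuracy table over (arm, method, stratum) cells.

    Produces, per stratum, the index-list accuracy per unique case (each
    patient counted once, since the index list is constant across
    replicates), the index accuracy per expanded row of each arm, and the
    accuracy of each combination method per arm.  Cells whose stratum is
    empty are emitted with denominator 0 and missing proportion rather
    than dropped silently.
    """
    if "stratum" not in rows.columns:
        raise ValueError("rows must carry a 'stratum' column")
    out: list[dict] = []

    def emit(arm: str, method: str, stratum: str, hits: pd.Series) -> None:
        if len(hits) == 0:
            out.append(
                {
                    "arm": arm,
                    "method": method,
                    "stratum": stratum,
                    "numerator": 0,
                    "denominator": 0,
                    "proportion": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
            return
        acc = accuracy_with_ci(hits.tolist(), level=level)
        out.append(
            {
                "arm": arm,
                "method": method,
                "stratum": stratum,
                "numerator": acc.numerator,
                "denominator": acc.denominator,
                "proportion": acc.proportion,
                "ci_low": acc.ci_low,
                "ci_high": acc.ci_high,
            }
        )

    per_case = rows.drop_duplicates(subset=["case_id"])
    for stratum in strata:
        emit(
            "index",
            "per_case",
            stratum,
            per_case.loc[_stratum_mask(per_case, stratum), "index_hit"],
        )
    arms = sorted(rows["arm"].unique())
    pairwise = [a for a in arms if a.startswith("2-system:")]
    groups: list[tuple[str, pd.DataFrame]] = []
    if len(pairwise) > 1:
        # pooled two-system framing: every (replicate, other-generator) row,
        # e.g. 103 cases x 2 replicates x 2 generators = 412 rows
        groups.append(("2-system", rows[rows["arm"].isin(pairwise)]))
    groups.extend((a, rows[rows["arm"] == a]) for a in arms)
    for arm, arm_rows in groups:
        for stratum in strata:
            sel = arm_rows.loc[_stratum_mask(arm_rows, stratum)]
            emit(arm, "index", stratum, sel["index_hit"])
            for method in COMBINATION_METHODS:
                emit(arm, method, stratum, sel[f"{method}_hit"])
    return pd.DataFrame(out)
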