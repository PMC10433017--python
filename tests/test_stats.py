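"""Tests of paired evaluation rows, exact CIs, McNemar and logistic fits."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ddxfusion import (
    CaseRecord,
    SeparationError,
    accuracy_with_ci,
    contains_correct,
    expand_rows,
    fit_logistic_shared,
    mcnemar_paired,
    summarize_strata,
)
from .helpers import make_list

D = [f"d{i:02d}" for i in range(40)]


def record(case, rep, truth, stratum, lists):
    return CaseRecord(case, rep, truth, stratum, {l.generator_id: l for l in lists})


# ---------------------------------------------------------------------------
# contains_correct


def test_contains_correct_is_membership_not_rank():
    for r in range(10):
        entries = D[:10]
        assert contains_correct(entries, entries[r])
    assert not contains_correct(D[:10], "absent")
    assert not contains_correct([], "x")  # empty shared list counts as a miss
    with pytest.raises(ValueError):
        contains_correct(D[:10], "")


# ---------------------------------------------------------------------------
# expand_rows


def test_minimal_design_one_pair_no_three_system():
    rec = record(
        "c1", "r1", "d00", "common",
        [make_list("index", D[:10]), make_list("second", D[5:15])],
    )
    rows = expand_rows([rec])
    assert list(rows["arm"]) == ["2-system:second"]
    assert rows.loc[0, "index_hit"] and not rows.loc[0, "hit_second"]
    assert rows.loc[0, "shared_count"] == 5


def test_expand_counts_match_study_design():
    recs = []
    for c in range(5):
        for r in range(2):
            recs.append(
                record(
                    f"c{c}", f"r{r}", "d00", "common",
                    [
                        make_list("index", D[:10]),
                        make_list("second", D[10:20]),
                        make_list("third", D[20:30]),
                    ],
                )
            )
    rows = expand_rows(recs)
    assert (rows["arm"].str.startswith("2-system")).sum() == 5 * 2 * 2
    assert (rows["arm"] == "3-system").sum() == 5 * 2


def test_expand_rejects_index_only_records():
    rec = record("c1", "r1", "d00", "common", [make_list("index", D[:10])])
    with pytest.raises(ValueError, match="c1"):
        expand_rows([rec])


def test_per_row_hit_logic_on_synthetic_rows(small_cohort_rows):
    """union hit ⇔ any single hit; shared hit ⇒ every single hit."""
    rows = small_cohort_rows
    three = rows[rows["arm"] == "3-system"]
    singles = three[["index_hit", "hit_second", "hit_third"]].astype(bool)
    assert (three["union_hit"] == singles.any(axis=1)).all()
    assert (~three["shared_hit"] | singles.all(axis=1)).all()
    for g in ("second", "third"):
        two = rows[rows["arm"] == f"2-system:{g}"]
        singles2 = two[["index_hit", f"hit_{g}"]].astype(bool)
        assert (two["union_hit"] == singles2.any(axis=1)).all()
        assert (~two["shared_hit"] | singles2.all(axis=1)).all()


# ---------------------------------------------------------------------------
# exact binomial CIs


@pytest.mark.parametrize(
    "k, n, lo_pct, hi_pct",
    [(47, 103, 36, 56), (133, 206, 58, 71)],
)
def test_clopper_pearson_reproduces_printed_intervals(k, n, lo_pct, hi_pct):
    acc = accuracy_with_ci([True] * k + [False] * (n - k))
    assert round(acc.ci_low * 100) == lo_pct
    assert round(acc.ci_high * 100) == hi_pct


def test_ci_boundaries_at_zero_and_full():
    zero = accuracy_with_ci([False] * 20)
    assert zero.ci_low == 0.0 and zero.proportion == 0.0
    full = accuracy_with_ci([True] * 20)
    assert full.ci_high == 1.0 and full.proportion == 1.0


def test_ci_matches_scipy_binomtest_oracle():
    for k, n in [(3, 17), (47, 103), (0, 9), (9, 9)]:
        acc = accuracy_with_ci([True] * k + [False] * (n - k))
        ci = sps.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        assert acc.ci_low == pytest.approx(ci.low, abs=1e-10)
        assert acc.ci_high == pytest.approx(ci.high, abs=1e-10)


def test_accuracy_requires_observations():
    with pytest.raises(ValueError):
        accuracy_with_ci([])


# ---------------------------------------------------------------------------
# McNemar


def pairs_from_counts(b, c, concordant=4):
    index = [True] * b + [False] * c + [True] * concordant
    combined = [False] * b + [True] * c + [True] * concordant
    return index, combined


def enumeration_p(b, c):
    """Two-sided exact p by enumerating every discordant-pair outcome."""
    n = b + c
    if n == 0:
        return 1.0
    m = min(b, c)
    count = sum(
        1 for seq in itertools.product([0, 1], repeat=n) if sum(seq) <= m
    )
    return min(1.0, 2.0 * count / 2**n)


def test_mcnemar_hand_example():
    idx, comb = pairs_from_counts(1, 5)
    res = mcnemar_paired(idx, comb)
    assert res.b == 1 and res.c == 5
    assert res.p_value == pytest.approx(0.21875)


def test_mcnemar_symmetric_or_concordant_is_one():
    idx, comb = pairs_from_counts(3, 3)
    assert mcnemar_paired(idx, comb).p_value == 1.0
    idx, comb = pairs_from_counts(0, 0, concordant=6)
    assert mcnemar_paired(idx, comb).p_value == 1.0


@pytest.mark.parametrize("b, c", [(0, 1), (2, 2), (1, 5), (0, 7), (4, 8), (6, 6), (0, 12)])
def test_mcnemar_exact_matches_enumeration(b, c):
    idx, comb = pairs_from_counts(b, c)
    assert mcnemar_paired(idx, comb).p_value == pytest.approx(enumeration_p(b, c))


def test_mcnemar_matches_statsmodels():
    for b, c in [(1, 5), (3, 9), (10, 4)]:
        idx, comb = pairs_from_counts(b, c)
        ours = mcnemar_paired(idx, comb).p_value
        table = [[4, b], [c, 0]]
        theirs = sm_mcnemar(table, exact=True).pvalue
        assert ours == pytest.approx(theirs)


def test_mcnemar_continuity_corrected_variant():
    idx, comb = pairs_from_counts(3, 12)
    res = mcnemar_paired(idx, comb, variant="continuity_corrected")
    assert res.statistic == pytest.approx((abs(3 - 12) - 1) ** 2 / 15)
    assert res.p_value == pytest.approx(float(sps.chi2.sf(res.statistic, 1)))


def test_mcnemar_rejects_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        mcnemar_paired([True], [True, False])


# ---------------------------------------------------------------------------
# logistic regression


def test_logistic_matches_direct_likelihood_optimum():
    rng = np.random.default_rng(42)
    x = rng.integers(0, 7, 400)
    y = rng.random(400) < 1 / (1 + np.exp(-(-1.0 + 0.3 * x)))
    fit = fit_logistic_shared(x, y)

    def nll(beta):
        eta = beta[0] + beta[1] * x
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    opt = minimize(nll, [0.0, 0.0], method="BFGS")
    assert nll([fit.beta0, fit.beta1]) == pytest.approx(opt.fun, abs=1e-6)


def test_logistic_binary_predictor_equals_cross_product_ratio():
    # counts per (x, hit): x=0 → 30 hits / 70 misses; x=1 → 60 hits / 40 misses
    x = [0] * 100 + [1] * 100
    y = [True] * 30 + [False] * 70 + [True] * 60 + [False] * 40
    fit = fit_logistic_shared(x, y)
    assert fit.odds_ratio == pytest.approx((60 * 70) / (40 * 30), rel=1e-6)


def test_logistic_degenerate_inputs_raise():
    with pytest.raises(ValueError, match="both outcome classes"):
        fit_logistic_shared([0, 1, 2, 3], [True, True, True, True])
    with pytest.raises(ValueError, match="distinct"):
        fit_logistic_shared([2, 2, 2, 2], [True, False, True, False])
    with pytest.raises(SeparationError, match="separation"):
        fit_logistic_shared([0, 0, 1, 1, 3, 3], [False, False, False, False, True, True])


def test_logistic_null_model_estimates_or_near_one():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 6, 5000)
    y = rng.random(5000) < 0.4  # independent of x
    fit = fit_logistic_shared(x, y)
    assert abs(fit.beta1) < 3 * fit.se_beta1
    assert fit.odds_ratio == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------------------
# stratified summary


def test_summary_cells_match_direct_recomputation(small_cohort_rows):
    table = summarize_strata(small_cohort_rows)
    three = small_cohort_rows[small_cohort_rows["arm"] == "3-system"]
    cell = table[
        (table["arm"] == "3-system")
        & (table["method"] == "union")
        & (table["stratum"] == "total")
    ].iloc[0]
    assert cell["proportion"] == pytest.approx(three["union_hit"].mean())
    common = three[three["stratum"] == "common"]
    cell_c = table[
        (table["arm"] == "3-system")
        & (table["method"] == "shared")
        & (table["stratum"] == "common")
    ].iloc[0]
    assert cell_c["proportion"] == pytest.approx(common["shared_hit"].mean())


def test_index_accuracy_identical_per_case_and_per_row(small_cohort_rows):
    """Replicate expansion duplicates index hits, preserving the proportion."""
    table = summarize_strata(small_cohort_rows)
    per_case = table[
        (table["arm"] == "index") & (table["method"] == "per_case") & (table["stratum"] == "total")
    ].iloc[0]
    per_row = table[
        (table["arm"] == "3-system") & (table["method"] == "index") & (table["stratum"] == "total")
    ].iloc[0]
    assert per_case["proportion"] == pytest.approx(per_row["proportion"])
    assert per_row["denominator"] == 2 * per_case["denominator"]


def test_empty_stratum_is_marked_not_zero():
    recs = []
    for c in range(3):
        recs.append(
            record(
                f"c{c}", "r1", "d00", "common",
                [make_list("index", D[:10]), make_list("second", D[10:20])],
            )
        )
    table = summarize_strata(expand_rows(recs))
    uncommon = table[table["stratum"] == "uncommon"]
    assert (uncommon["denominator"] == 0).all()
    assert uncommon["proportion"].isna().all()


def test_clopper_pearson_coverage_is_conservative():
    """95% exact intervals cover the true p in at least ~95% of trials."""
    rng = np.random.default_rng(99)
    p, n, trials = 0.46, 103, 1000
    covered = 0
    ks = rng.binomial(n, p, trials)
    for k in ks:
        acc = accuracy_with_ci([True] * int(k) + [False] * (n - int(k)))
        covered += acc.ci_low <= p <= acc.ci_high
    # MC standard error of the coverage estimate is about 0.7%
    assert covered / trials >= 0.95 - 0.02
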