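"""Confusion metrics, exact tests and power estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prexstim.datasets import load_validation_cohort, validation_outcomes
from prexstim.errors import InputError
from prexstim.evaluation import (
    ConfusionCounts,
    binomial_noninferiority_region,
    cohort_summary,
    confusion_matrix,
    fisher_exact,
    mann_whitney,
    noninferiority_power,
    performance,
    two_proportion_test,
)


class TestConfusion:
    def test_validation_cohort_outcome_tally(self):
        # six real-life responders of whom exactly two were missed; both
        # non-responders correctly identified
        truth = validation_outcomes()
        pred = list(truth)
        pred[4] = pred[5] = "non-responder"  # the two missed responders
        c = confusion_matrix(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 2, 2)

    def test_perfect_prediction(self):
        c = confusion_matrix([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_matches_loop_oracle(self, pairs):
        pred = [p for p, _ in pairs]
        truth = [t for _, t in pairs]
        c = confusion_matrix(pred, truth)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for p, t in pairs:
            key = ("t" if p == t else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (
            tally["tp"], tally["fp"], tally["fn"], tally["tn"]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            confusion_matrix([1], [1, 0])


class TestPerformance:
    def test_published_validation_metrics(self):
        perf = performance(ConfusionCounts(tp=4, fp=0, fn=2, tn=2))
        assert perf.accuracy == 75.0
        assert perf.sensitivity == pytest.approx(66.667, abs=1e-2)
        assert perf.specificity == 100.0
        assert perf.rounded() == (75, 67, 100)

    def test_perfect(self):
        assert performance(ConfusionCounts(3, 0, 0, 2)).rounded() == (
            100, 100, 100,
        )

    def test_undefined_metric_flagged_not_zero(self):
        perf = performance(ConfusionCounts(tp=3, fp=0, fn=1, tn=0))
        assert perf.specificity is None
        assert perf.rounded()[2] is None

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_matches_formula(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        perf = performance(ConfusionCounts(tp, fp, fn, tn))
        assert perf.accuracy == pytest.approx(
            100 * (tp + tn) / (tp + fp + fn + tn)
        )
        if tp + fn:
            assert perf.sensitivity == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert perf.specificity == pytest.approx(100 * tn / (tn + fp))


def _fisher_enumeration(table):
    """Independent oracle: sum hypergeometric point probabilities <= obs."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(k, n, row1, col1)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    @pytest.mark.parametrize(
        "table, printed",
        [([[36, 24], [0, 8]], 0.001), ([[14, 46], [5, 3]], 0.034)],
    )
    def test_published_cohort_comparisons(self, table, printed):
        assert round(fisher_exact(table), 3) == printed

    def test_equal_proportions_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            table = [[a, b], [c, d]]
            assert fisher_exact(table) == pytest.approx(
                _fisher_enumeration(table), abs=1e-9
            )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(InputError):
            fisher_exact([[0, 0], [1, 2]])


def _mw_enumeration(x, y):
    """Exact two-sided p by enumerating all rank splits."""
    nx = len(x)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    stat_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(combined)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= stat_obs - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_tiny_sample_exact_value(self):
        assert mann_whitney([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        x, y = rng.random(5), rng.random(7)
        assert mann_whitney(x, y) == pytest.approx(mann_whitney(y, x))

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(5):
            x = rng.random(5)
            y = rng.random(6)
            assert mann_whitney(x, y) == pytest.approx(
                _mw_enumeration(x, y), abs=1e-9
            )

    def test_asymptotic_close_to_exact(self, rng):
        worst = 0.0
        for _ in range(20):
            x, y = rng.random(8), rng.random(8)
            exact = _mw_enumeration(x, y)
            approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
            worst = max(worst, abs(exact - approx))
        assert worst <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1.0])


class TestTwoProportion:
    def test_equal_proportions(self):
        assert two_proportion_test(3, 6, 5, 10) == pytest.approx(1.0)

    def test_symmetry(self):
        assert two_proportion_test(6, 8, 19, 22) == pytest.approx(
            two_proportion_test(19, 22, 6, 8)
        )

    def test_matches_statsmodels_pooled_z(self):
        from statsmodels.stats.proportion import proportions_ztest

        _, oracle = proportions_ztest([6, 19], [8, 22])
        assert two_proportion_test(6, 8, 19, 22) == pytest.approx(oracle)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            two_proportion_test(5, 4, 1, 2)


class TestNoninferiorityPower:
    def test_exact_rejection_region_and_power(self):
        # margin 0.70, n=8, alpha=0.06: only a perfect 8/8 rejects, so
        # power = p_true^8
        assert binomial_noninferiority_region(8, 0.70, 0.06) == 8
        est = noninferiority_power(0.86, 8, 0.70, alpha=0.06,
                                   n_sim=20_000, seed=5)
        assert est.exact == pytest.approx(0.86**8, abs=1e-12)
        assert abs(est.power - est.exact) <= 3 * est.mc_se

    def test_size_bounded_by_alpha(self):
        est = noninferiority_power(0.70, 8, 0.70, alpha=0.06,
                                   n_sim=5000, seed=1)
        assert est.exact <= 0.06

    def test_monotone_in_true_accuracy(self):
        powers = [
            noninferiority_power(p, 8, 0.70, alpha=0.06, n_sim=100,
                                 seed=0).exact
            for p in (0.7, 0.8, 0.9, 0.99)
        ]
        assert powers == sorted(powers)

    def test_mc_matches_closed_form_over_random_draws(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            margin = float(rng.uniform(0.3, 0.9))
            p_true = float(rng.uniform(margin, 1.0))
            est = noninferiority_power(
                p_true, n, margin, alpha=0.05, n_sim=4000,
                seed=int(rng.integers(2**31)),
            )
            assert abs(est.power - est.exact) <= 3 * max(est.mc_se, 1 / 4000)


class TestCohortSummary:
    def test_validation_descriptives_match_published_table(self):
        table = load_validation_cohort()
        ages = table["age_onset"]
        assert ages.median() == 16
        assert (ages.min(), ages.max()) == (7, 60)
        assert table["VPA"].sum() == 5
        assert table["LEV"].sum() == 0

    def test_two_cohort_summary(self, rng):
        val = load_validation_cohort()
        synth_training = val.sample(
            n=20, replace=True, random_state=7
        ).reset_index(drop=True)
        combined = []
        for name, frame in (("training", synth_training), ("validation", val)):
            part = frame[["age_onset", "VPA"]].copy()
            part["cohort"] = name
            combined.append(part)
        summary = cohort_summary(pd.concat(combined, ignore_index=True))
        row = summary[summary["covariate"] == "age_onset"].iloc[0]
        assert row["validation"] == "16 (7-60)"
        assert row["kind"] == "numeric"
        vpa = summary[summary["covariate"] == "VPA"].iloc[0]
        assert vpa["validation"] == "5 (63%)"
        assert 0 <= vpa["p_value"] <= 1

    def test_single_cohort_rejected(self):
        frame = pd.DataFrame({"cohort": ["a", "a"], "x": [1.0, 2.0]})
        with pytest.raises(InputError):
            cohort_summary(frame)
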