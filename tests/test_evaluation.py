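"""Screening statistics: ROC vs pair-counting oracle, Youden threshold,
confusion arithmetic, interval estimators, and risk stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from fundusfocus.evaluation import (
    ThresholdPolicy,
    bootstrap_rate_ci,
    byar_poisson_ci,
    chi_square_2x2,
    compute_roc,
    confusion_from_counts,
    confusion_from_scores,
    micro_macro_auroc,
    odds_ratio_with_ci,
    records_to_table,
    select_optimal_threshold,
    stratify_by_median,
)
from fundusfocus.exceptions import ParameterError, StratificationError


def pair_counting_auc(scores, labels):
    """Brute-force Mann-Whitney concordance (ties counted one half)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        roc = compute_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_independent_scores_give_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert compute_roc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_four_point_toy_matches_exhaustive_pairs(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert compute_roc(scores, labels).auc == pytest.approx(
            pair_counting_auc(scores, labels)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_pair_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        scores = rng.integers(0, 6, n) / 5.0  # coarse grid forces ties
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        assert compute_roc(scores, labels).auc == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            compute_roc([0.5, 0.6], [1, 1])

    def test_sensitivity_monotone_along_curve(self):
        rng = np.random.default_rng(2)
        roc = compute_roc(rng.random(60), rng.integers(0, 2, 60))
        assert (np.diff(roc.sensitivity) >= 0).all()  # thresholds descend


class TestYouden:
    def test_separable_scores_reach_j_of_one(self):
        roc = compute_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        thr = select_optimal_threshold(roc)
        assert 0.2 < thr <= 0.8
        cm = confusion_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], thr)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_all_equal_scores_warn_and_return_degenerate(self):
        roc = compute_roc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            thr = select_optimal_threshold(roc)
        assert thr == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_never_beaten_by_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = rng.random(30).round(2)
        labels = np.r_[1, 0, rng.integers(0, 2, 28)]
        roc = compute_roc(scores, labels)
        thr = select_optimal_threshold(roc)
        best = confusion_from_scores(scores, labels, thr)
        best_j = best.sensitivity + best.specificity - 1
        for t in np.unique(scores):
            cm = confusion_from_scores(scores, labels, t)
            assert cm.sensitivity + cm.specificity - 1 <= best_j + 1e-12

    def test_policy_modes_order_thresholds(self):
        rng = np.random.default_rng(4)
        scores = rng.random(50)
        labels = np.r_[1, 0, rng.integers(0, 2, 48)]
        roc = compute_roc(scores, labels)
        lo = ThresholdPolicy("screening").apply(roc)
        mid = ThresholdPolicy("youden").apply(roc)
        hi = ThresholdPolicy("hospital").apply(roc)
        assert lo <= mid <= hi


class TestConfusion:
    def test_glau_validation_sentence(self):
        cm = confusion_from_counts(p=2198, tp=2115, n=6926, fp=278)
        assert round(100 * cm.accuracy, 2) == 96.04
        assert round(100 * cm.sensitivity) == 96

    def test_amd_validation_sentence(self):
        cm = confusion_from_counts(p=180, tp=168, n=8944, fp=110)
        assert round(100 * cm.accuracy, 2) == 98.66
        assert round(100 * cm.sensitivity) == 93

    def test_perfect_counts_give_full_accuracy(self):
        cm = confusion_from_counts(p=10, tp=10, n=10, fp=0)
        assert cm.accuracy == 1.0

    def test_preconditions_enforced(self):
        with pytest.raises(ParameterError):
            confusion_from_counts(p=5, tp=6, n=10, fp=0)
        with pytest.raises(ParameterError):
            confusion_from_counts(p=5, tp=5, n=10, fp=11)


class TestMicroMacro:
    def _toy(self):
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        frame = pd.DataFrame(
            {
                "a": [0.8, 0.6, 0.3, 0.1, 0.2, 0.1],
                "b": [0.1, 0.3, 0.6, 0.8, 0.1, 0.2],
                "c": [0.1, 0.1, 0.1, 0.1, 0.7, 0.7],
            }
        )
        return frame, labels

    def test_perfect_classifier_gives_one_one(self):
        frame, labels = self._toy()
        micro, macro = micro_macro_auroc(frame, labels)
        assert micro == 1.0 and macro == 1.0

    def test_three_class_toy_matches_hand_pair_counting(self):
        labels = np.array(["a", "b", "a", "c", "b", "c"])
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.random((6, 3)), columns=["a", "b", "c"])
        micro, macro = micro_macro_auroc(frame, labels)

        def pair_auc(y, s):
            pos = s[y == 1]
            neg = s[y == 0]
            tot = sum(
                1.0 if p > n else (0.5 if p == n else 0.0)
                for p in pos
                for n in neg
            )
            return tot / (len(pos) * len(neg))

        per_class = [
            pair_auc((labels == c).astype(int), frame[c].to_numpy())
            for c in "abc"
        ]
        assert macro == pytest.approx(np.mean(per_class))
        flat_y = np.concatenate([(labels == c).astype(int) for c in "abc"])
        flat_s = np.concatenate([frame[c].to_numpy() for c in "abc"])
        assert micro == pytest.approx(pair_auc(flat_y, flat_s))

    def test_absent_class_excluded_with_warning(self):
        frame, labels = self._toy()
        labels = np.where(labels == "c", "a", labels)
        with pytest.warns(UserWarning, match="absent"):
            micro, macro = micro_macro_auroc(frame, labels)
        assert 0.0 <= macro <= 1.0


class TestByar:
    def test_zero_events_lower_bound_is_zero(self):
        lo, hi = byar_poisson_ci(0)
        assert lo == 0.0 and hi > 0

    def test_matches_exact_poisson_inversion_within_2pct(self):
        for x in (5, 10, 50):
            lo, hi = byar_poisson_ci(x)
            exact_lo = sp_stats.chi2.ppf(0.025, 2 * x) / 2
            exact_hi = sp_stats.chi2.ppf(0.975, 2 * (x + 1)) / 2
            assert lo == pytest.approx(exact_lo, rel=0.02)
            assert hi == pytest.approx(exact_hi, rel=0.02)

    def test_x10_reference_values(self):
        lo, hi = byar_poisson_ci(10)
        assert lo == pytest.approx(4.79, abs=0.01)
        assert hi == pytest.approx(18.39, abs=0.01)

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            byar_poisson_ci(-1)


class TestOddsRatio:
    def test_equal_odds_give_unit_ratio(self):
        or_, lo, hi = odds_ratio_with_ci(10, 20, 5, 10)
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_arithmetic(self):
        or_, _, _ = odds_ratio_with_ci(10, 5, 2, 8)
        assert or_ == pytest.approx(8.0)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 30, 4)
            or_, lo, hi = odds_ratio_with_ci(a, b, c, d)
            assert lo <= or_ <= hi

    def test_zero_cell_haldane_corrected_finite(self):
        or_, lo, hi = odds_ratio_with_ci(10, 0, 0, 10)
        assert np.isfinite(or_) and or_ > 1
        assert np.isfinite(hi)


class TestChiSquare:
    def test_balanced_table_gives_zero_statistic(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_matches_textbook_formula(self):
        a, b, c, d = 20, 10, 10, 20
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert stat == pytest.approx(expected)

    def test_strong_association_is_significant(self):
        _, p = chi_square_2x2([[90, 10], [10, 90]])
        assert p < 0.001

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestBootstrap:
    def test_degenerate_flags(self):
        assert bootstrap_rate_ci([1, 1, 1], seed=0) == (1.0, 1.0)
        assert bootstrap_rate_ci([0, 0, 0], seed=0) == (0.0, 0.0)

    def test_binomial_closed_form_comparison(self):
        flags = np.r_[np.ones(200), np.zeros(200)]
        lo, hi = bootstrap_rate_ci(flags, reps=1000, seed=1)
        # normal-approximation binomial interval: 0.5 +/- 1.96*sqrt(pq/n)
        assert lo == pytest.approx(0.451, abs=0.015)
        assert hi == pytest.approx(0.549, abs=0.015)
        assert lo < 0.5 < hi

    def test_reproducible_per_seed(self):
        flags = np.random.default_rng(0).integers(0, 2, 50)
        assert bootstrap_rate_ci(flags, seed=3) == bootstrap_rate_ci(flags, seed=3)


def make_table(scores, labels, disease="GLAU"):
    return pd.DataFrame(
        {
            "image_id": [f"i{k}" for k in range(len(scores))],
            "patient_id": [f"p{k}" for k in range(len(scores))],
            "true_label": [disease if l else "NORM" for l in labels],
            f"score_{disease}": scores,
        }
    )


class TestStratification:
    def test_scores_equal_labels_give_large_significant_or(self):
        labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
        table = make_table(labels.astype(float), labels)
        report = stratify_by_median(table, "GLAU", bootstrap_reps=200, seed=0)
        assert report.p_value < 0.001
        assert np.isfinite(report.odds_ratio) and report.odds_ratio > 100

    def test_two_observations_split_one_and_one(self):
        table = make_table([0.2, 0.9], [0, 1])
        report = stratify_by_median(table, "GLAU", bootstrap_reps=50, seed=0)
        assert report.low.n == 1 and report.high.n == 1

    def test_identical_scores_rejected(self):
        table = make_table([0.5] * 10, [0, 1] * 5)
        with pytest.raises(StratificationError):
            stratify_by_median(table, "GLAU")

    def test_ties_assigned_to_high_risk_group(self):
        table = make_table([0.1, 0.5, 0.5, 0.9], [0, 0, 1, 1])
        report = stratify_by_median(table, "GLAU", bootstrap_reps=50, seed=0)
        assert report.high.n == 3  # both 0.5 scores sit at the median

    def test_null_cohort_or_ci_covers_one(self):
        """Independent scores: the OR interval should cover 1 in >= 90%
        of replicated cohorts."""
        rng = np.random.default_rng(7)
        covered = 0
        reps = 40
        for _ in range(reps):
            scores = rng.random(1000)
            labels = rng.integers(0, 2, 1000)
            table = make_table(scores, labels)
            report = stratify_by_median(table, "GLAU", bootstrap_reps=20, seed=0)
            covered += report.or_ci[0] <= 1.0 <= report.or_ci[1]
        assert covered / reps >= 0.9

    def test_or_recovery_on_known_risk_cohorts(self):
        """With group membership driving outcome odds, the log-OR estimate
        lands within 3 standard errors of truth in >= 95% of reps."""
        rng = np.random.default_rng(11)
        true_or = 6.0
        hits, reps = 0, 40
        for _ in range(reps):
            n = 600
            scores = rng.random(n)
            high = scores >= np.median(scores)
            p_low = 0.15
            odds_high = true_or * p_low / (1 - p_low)
            p_high = odds_high / (1 + odds_high)
            labels = np.where(high, rng.random(n) < p_high, rng.random(n) < p_low)
            table = make_table(scores, labels.astype(int))
            report = stratify_by_median(table, "GLAU", bootstrap_reps=20, seed=0)
            a = report.high.positive_events
            b = report.high.n - a
            c = report.low.positive_events
            d = report.low.n - c
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            hits += abs(np.log(report.odds_ratio) - np.log(true_or)) <= 3 * se
        assert hits / reps >= 0.95

    def test_report_frame_has_table_shape(self):
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        rng = np.random.default_rng(0)
        scores = np.clip(labels * 0.6 + rng.random(40) * 0.4, 0, 1)
        table = make_table(scores, labels)
        frame = stratify_by_median(
            table, "GLAU", bootstrap_reps=50, seed=0
        ).to_frame()
        assert list(frame["subset"]) == ["low risk", "high risk"]
        assert {"positive_rate_95ci", "OR_95ci", "p_value"} <= set(frame.columns)
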