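import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from sumscan.cohort_stats import (
    ClassifierMetrics,
    ConfusionMatrix,
    ContingencyTable2x2,
    chi_square_2x2,
    confusion_metrics,
    evaluate_classifier,
    fisher_exact_two_sided,
    format_percent,
    gene_gain_loss_frequencies,
    mann_whitney_u,
)
from sumscan.target_scoring import Benefit, SumscanClass, SumscanResult

from conftest import make_call


class TestFisherExact:
    def test_second_line_table_value(self):
        # 2x2 with strong association; frozen against independent integer
        # enumeration of the hypergeometric distribution
        p = fisher_exact_two_sided([[10, 2], [2, 12]])
        assert p == pytest.approx(0.0011, abs=5e-5)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided([[1, 1], [1, 1]]) == 1.0

    def test_large_delta_table_value(self):
        # brute-force enumeration over the 9 tables with these margins
        p = fisher_exact_two_sided([[8, 0], [3, 14]])
        assert p == pytest.approx(1.53e-4, rel=5e-3)

    def test_degenerate_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_two_sided([[0, 0], [3, 4]]) == 1.0

    def test_transposition_and_double_swap_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = fisher_exact_two_sided([[a, b], [c, d]])
                assert fisher_exact_two_sided([[a, c], [b, d]]) == pytest.approx(p)
                assert fisher_exact_two_sided([[d, c], [b, a]]) == pytest.approx(p)

    def test_doubling_rule_bounds_point_probability_rule(self):
        # doubling can only be >= the point-probability p
        for table in ([[10, 2], [2, 12]], [[5, 1], [2, 5]], [[3, 3], [3, 3]]):
            assert fisher_exact_two_sided(table, rule="doubling") >= (
                fisher_exact_two_sided(table) - 1e-12
            )

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            mine = fisher_exact_two_sided([[a, b], [c, d]])
            ref = scipy_fisher([[a, b], [c, d]]).pvalue
            assert mine == pytest.approx(ref, abs=1e-12)


class TestChiSquare:
    def test_discovery_ttc4_split(self):
        # 5/6 vs 2/7 high-TTC split; uncorrected Pearson chi-square
        stat, p = chi_square_2x2([[5, 1], [2, 5]])
        assert stat == pytest.approx(3.90, abs=0.01)
        assert p == pytest.approx(0.048, abs=5e-4)

    def test_no_association(self):
        stat, p = chi_square_2x2([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == 1.0

    def test_doubling_counts_doubles_statistic(self):
        stat1, p1 = chi_square_2x2([[5, 1], [2, 5]])
        stat2, p2 = chi_square_2x2([[10, 2], [4, 10]])
        assert stat2 == pytest.approx(2 * stat1)
        assert p2 < p1

    def test_zero_expected_cell_recommends_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi_square_2x2([[0, 0], [3, 4]])

    def test_yates_correction_shrinks_statistic(self):
        stat, _ = chi_square_2x2([[5, 1], [2, 5]])
        stat_corr, _ = chi_square_2x2([[5, 1], [2, 5]], continuity_correction=True)
        assert stat_corr < stat


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_symmetry_under_group_swap(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(b, a)
        assert p1 == pytest.approx(p2)

    def test_identical_groups_maximal_p(self):
        _, p = mann_whitney_u([1.0, 2.0, 5.0], [1.0, 2.0, 5.0], exact=False)
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_label_enumeration(self, rng):
        """Exact p equals full enumeration of group-label assignments."""

        def enumeration_p(a_vals, b_vals):
            pooled = list(a_vals) + list(b_vals)
            na, n = len(a_vals), len(pooled)

            def ustat(idx):
                a_set = [pooled[i] for i in idx]
                b_set = [pooled[i] for i in range(n) if i not in idx]
                return sum(
                    (x > y) + 0.5 * (x == y) for x in a_set for y in b_set
                )

            u_obs = ustat(tuple(range(na)))
            us = [ustat(i) for i in itertools.combinations(range(n), na)]
            le = sum(u <= u_obs for u in us) / len(us)
            ge = sum(u >= u_obs for u in us) / len(us)
            return min(1.0, 2 * min(le, ge))

        for _ in range(25):
            na, nb = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            pooled = rng.permutation(na + nb) + 1.0
            a, b = pooled[:na], pooled[na:]
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(enumeration_p(a, b), abs=1e-12)


class TestConfusionMetrics:
    def test_pooled_regorafenib_counts(self):
        m = confusion_metrics(ConfusionMatrix(tp=10, fn=1, fp=5, tn=9))
        assert m.sensitivity == pytest.approx(0.909, abs=5e-4)
        assert m.accuracy == pytest.approx(0.76, abs=5e-3)

    def test_validation_two_counts(self):
        m = confusion_metrics(ConfusionMatrix(tp=14, fn=6, fp=2, tn=11))
        assert m.sensitivity == pytest.approx(0.70, abs=5e-3)
        assert m.accuracy == pytest.approx(0.758, abs=5e-4)
        assert m.ppv == pytest.approx(0.875, abs=5e-4)
        assert m.npv == pytest.approx(0.647, abs=5e-4)

    def test_undefined_denominator_is_missing(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=1, tn=1))
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(0.5)

    def test_accuracy_identity(self, rng):
        """accuracy == (sens*P + spec*N') / (P + N') whenever both defined."""
        for _ in range(100):
            tp, fn, fp, tn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + fn == 0 or fp + tn == 0:
                continue
            m = confusion_metrics(ConfusionMatrix(tp, fn, fp, tn))
            p_count, n_count = tp + fn, fp + tn
            expected = (m.sensitivity * p_count + m.specificity * n_count) / (
                p_count + n_count
            )
            assert m.accuracy == pytest.approx(expected)

    def test_format_percent_half_up(self):
        assert format_percent(0.9090909) == "90.9"
        assert format_percent(0.7585) == "75.9"  # half-up at the boundary
        assert format_percent(None) == "NA"


def _result(sample, favorable, positive):
    return SumscanResult(
        sample_id=sample,
        drug="regorafenib",
        ttc=5 if favorable else 1,
        ttl=0,
        sumscan_class=SumscanClass.FAVORABLE if favorable else SumscanClass.UNFAVORABLE,
        benefit=Benefit.POSITIVE if positive else Benefit.NEGATIVE,
    )


class TestEvaluateClassifier:
    def test_count_mapping(self):
        results = (
            [_result(f"A{i}", True, True) for i in range(10)]
            + [_result("B0", False, True)]
            + [_result(f"C{i}", True, False) for i in range(5)]
            + [_result(f"D{i}", False, False) for i in range(9)]
        )
        cm, m = evaluate_classifier(results)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 1, 5, 9)
        assert m.sensitivity == pytest.approx(10 / 11)

    def test_all_correct_is_perfect(self):
        results = [_result("A", True, True), _result("B", False, False)]
        _, m = evaluate_classifier(results)
        assert m.accuracy == 1.0

    def test_unlabeled_result_named_in_error(self):
        bad = SumscanResult("S9", "regorafenib", 5, 0, SumscanClass.FAVORABLE)
        with pytest.raises(ValueError, match="S9"):
            evaluate_classifier([bad])

    def test_permuted_labels_give_base_rate_accuracy(self, rng):
        """Under random label permutation the mean accuracy approaches the
        agreement expected by chance from the marginals."""
        favorables = rng.random(40) < 0.5
        positives = rng.random(40) < 0.4
        accs = []
        for _ in range(500):
            perm = rng.permutation(40)
            results = [
                _result(f"S{i}", bool(favorables[i]), bool(positives[perm[i]]))
                for i in range(40)
            ]
            accs.append(evaluate_classifier(results)[1].accuracy)
        f = favorables.mean()
        p = positives.mean()
        chance = f * p + (1 - f) * (1 - p)
        assert np.mean(accs) == pytest.approx(chance, abs=0.03)


class TestGeneFrequencies:
    def _cohort(self):
        calls, labels = {}, {}
        # 9/11 positive tumors gain DDR2; 2/14 negative tumors do
        for i in range(11):
            s = f"P{i}"
            calls[s] = [
                make_call("DDR2", 0.7 if i < 9 else 0.0, s),
                make_call("EPHA2", 0.0, s),
            ]
            labels[s] = Benefit.POSITIVE
        for i in range(14):
            s = f"N{i}"
            calls[s] = [
                make_call("DDR2", 0.7 if i < 2 else 0.0, s),
                make_call("EPHA2", -0.7 if i < 6 else 0.0, s),
            ]
            labels[s] = Benefit.NEGATIVE
        return calls, labels

    def test_gain_frequencies_by_class(self):
        calls, labels = self._cohort()
        res = gene_gain_loss_frequencies(calls, labels, "DDR2")
        assert res.freq_gain_pos == pytest.approx(9 / 11)
        assert res.freq_gain_neg == pytest.approx(2 / 14)
        assert res.fisher_p_gain < 0.05

    def test_loss_frequencies_by_class(self):
        calls, labels = self._cohort()
        res = gene_gain_loss_frequencies(calls, labels, "EPHA2")
        assert res.freq_loss_pos == 0.0
        assert res.freq_loss_neg == pytest.approx(6 / 14)

    def test_neutral_gene_everywhere(self):
        calls, labels = self._cohort()
        for sample in calls:
            calls[sample].append(make_call("KIT", 0.0, sample))
        res = gene_gain_loss_frequencies(calls, labels, "KIT")
        assert res.freq_gain_pos == res.freq_gain_neg == 0.0
        assert res.fisher_p_gain == 1.0

    def test_absent_gene_errors(self):
        calls, labels = self._cohort()
        with pytest.raises(KeyError, match="NRAS"):
            gene_gain_loss_frequencies(calls, labels, "NRAS")
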