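import copy

import numpy as np
import pytest

import frfiwsa as fw

from .conftest import random_kb
from .oracles import (averages_oracle, cfci_oracle, ci_oracle,
                      cofiring_oracle, rule_stats_oracle)


@pytest.fixture()
def toy_kb_and_data(toy, toy_hand_kb):
    dataset, _ = toy
    return toy_hand_kb, dataset


class TestRuleStats:
    def test_coverage_accuracy_goodness_on_clean_rules(self, toy_kb_and_data):
        kb, dataset = toy_kb_and_data
        stats = fw.rule_stats(kb, dataset)
        for s in stats:
            # each hand rule covers its own class half: 8 of 16 samples
            assert s.n_con == 8
            assert s.r_cov == pytest.approx(0.5)
            assert s.r_acc == pytest.approx(1.0)
            assert s.r_gud == pytest.approx(1.0)

    def test_uncovered_rule_flagged_not_crashed(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        kb = random_kb(dataset.n_genes, 2, 3, ranges, rng)
        kb.rules[0].selected = 0
        s = fw.rule_stats(kb, dataset)[0]
        assert not s.acc_defined and not s.gud_defined
        assert s.r_acc == 0.0 and s.r_gud == 0.0

    def test_matches_accumulating_loop_oracle(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        for _ in range(5):
            kb = random_kb(dataset.n_genes, 2, 3, ranges, rng)
            got = fw.rule_stats(kb, dataset)
            want = rule_stats_oracle(kb, dataset)
            for g, w in zip(got, want):
                assert g.n_con == w["n_con"] and g.n_pro == w["n_pro"]
                assert g.r_cov == pytest.approx(w["r_cov"], abs=1e-12)
                assert g.r_acc == pytest.approx(w["r_acc"], abs=1e-12)
                assert g.r_gud == pytest.approx(w["r_gud"], abs=1e-12)
                assert g.tcs_fd == pytest.approx(w["tcs"], abs=1e-12)


class TestRulesetAverages:
    def test_premise_and_firing_averages(self, toy_kb_and_data):
        kb, dataset = toy_kb_and_data
        avg = fw.ruleset_averages(kb, dataset)
        assert avg.n_rules == 2
        assert avg.a_rl == pytest.approx(1.0)      # one premise per rule
        assert avg.t_fr == 16                      # each rule fires on half
        assert avg.a_fr == pytest.approx(8.0)
        assert 0.0 <= avg.a_cfd <= 1.0

    def test_matches_pairwise_loop_oracle(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        for _ in range(5):
            kb = random_kb(dataset.n_genes, 2, 3, ranges, rng)
            if not any(r.is_active for r in kb.rules):
                continue
            got = fw.ruleset_averages(kb, dataset)
            want = averages_oracle(kb, dataset)
            assert got.t_rl == want["t_rl"] and got.t_fr == want["t_fr"]
            assert got.a_fd == pytest.approx(want["a_fd"], abs=1e-12)
            assert got.a_cfd == pytest.approx(want["a_cfd"], abs=1e-12)

    def test_empty_ruleset_rejected(self, toy, toy_hand_kb):
        dataset, _ = toy
        kb = copy.deepcopy(toy_hand_kb)
        for rule in kb.rules:
            rule.selected = 0
        with pytest.raises(ValueError):
            fw.ruleset_averages(kb, dataset)


class TestCofiring:
    def test_diagonal_zero_and_symmetry(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        kb = random_kb(dataset.n_genes, 2, 4, ranges, rng)
        report = fw.cofiring_matrix(kb, dataset)
        assert np.all(np.diag(report.cf) == 0.0)
        np.testing.assert_allclose(report.cf, report.cf.T, atol=1e-15)
        assert np.all(report.cf >= 0.0)

    def test_substitution_example(self):
        # SF = 2, IF_i = 4, IF_j = 5 -> CF = 0.1
        assert 2 / (4 * 5) == pytest.approx(0.1)

    def test_disjoint_rules_never_cofire(self, toy_kb_and_data):
        kb, dataset = toy_kb_and_data   # low/high rules cover disjoint halves
        report = fw.cofiring_matrix(kb, dataset)
        assert np.all(report.cf == 0.0)
        assert list(report.if_counts) == [8, 8]

    def test_matches_double_loop_oracle(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        for _ in range(5):
            kb = random_kb(dataset.n_genes, 2, 3, ranges, rng)
            report = fw.cofiring_matrix(kb, dataset)
            cf, sf, iff = cofiring_oracle(kb, dataset)
            np.testing.assert_allclose(report.cf, cf, atol=1e-12)
            np.testing.assert_array_equal(report.sf, sf)
            np.testing.assert_array_equal(report.if_counts, iff)


class TestComprehensibility:
    def test_no_cofiring_gives_full_score(self, toy_kb_and_data):
        kb, dataset = toy_kb_and_data
        report = fw.cofiring_matrix(kb, dataset)
        ci, cfci, _, _ = fw.comprehensibility(report, threshold=0.5)
        assert ci == 0.0 and cfci == 1.0

    def test_index_above_threshold_zeroes_score(self):
        assert cfci_oracle(0.7, 0.5) == 0.0
        assert cfci_oracle(0.2, 0.5) == pytest.approx(0.6)

    def test_hand_filled_three_rule_example(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        kb = random_kb(dataset.n_genes, 2, 3, ranges, rng)
        report = fw.cofiring_matrix(kb, dataset)
        ci, cfci, ci_rows, _ = fw.comprehensibility(report, threshold=0.5)
        want_ci = ci_oracle(report.cf, list(report.premises))
        assert ci == pytest.approx(want_ci, abs=1e-12)
        assert cfci == pytest.approx(cfci_oracle(want_ci, 0.5), abs=1e-12)
        assert ci_rows.sum() == pytest.approx(want_ci, abs=1e-12)

    def test_invariant_under_rule_reordering(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        kb = random_kb(dataset.n_genes, 2, 3, ranges, rng)
        ci_a, _, _, _ = fw.comprehensibility(
            fw.cofiring_matrix(kb, dataset), threshold=0.3)
        kb.rules = kb.rules[::-1]
        ci_b, _, _, _ = fw.comprehensibility(
            fw.cofiring_matrix(kb, dataset), threshold=0.3)
        assert ci_a == pytest.approx(ci_b, abs=1e-12)

    def test_threshold_domain_checked(self, toy_kb_and_data):
        kb, dataset = toy_kb_and_data
        report = fw.cofiring_matrix(kb, dataset)
        with pytest.raises(ValueError):
            fw.comprehensibility(report, threshold=0.0)


class TestSimplify:
    def test_duplicate_rules_fused_without_accuracy_loss(self, toy,
                                                         toy_hand_kb):
        dataset, _ = toy
        kb = copy.deepcopy(toy_hand_kb)
        kb.rules.append(copy.deepcopy(kb.rules[0]))    # exact duplicate
        before = fw.evaluate_kb(kb, dataset)
        out = fw.simplify_rules(kb, dataset)
        after = fw.evaluate_kb(out, dataset)
        assert after.rs < before.rs
        assert after.accuracy >= before.accuracy

    def test_never_firing_rule_eliminated(self, toy, toy_hand_kb):
        dataset, _ = toy
        kb = copy.deepcopy(toy_hand_kb)
        dead = np.zeros(dataset.n_genes, dtype=int)
        dead[1] = 2
        # medium term of a noise gene collapsed to a single off-data point
        lo, hi = float(dataset.values[1].min()), float(dataset.values[1].max())
        mid = lo + 0.51234 * (hi - lo)
        assert mid not in dataset.values[1]
        kb.mfs[1] = fw.MembershipPointSet(
            (lo, lo, mid, mid, mid, mid, mid, hi, hi))
        kb.rules.append(fw.Rule(1, dead, 1))
        assert fw.evaluate_kb(kb, dataset).rs == 3
        out = fw.simplify_rules(kb, dataset)
        assert fw.evaluate_kb(out, dataset).rs == 2

    def test_training_accuracy_never_decreases(self, toy, rng):
        dataset, _ = toy
        ranges = [(float(r.min()), float(r.max())) for r in dataset.values]
        for _ in range(5):
            kb = random_kb(dataset.n_genes, 2, 3, ranges, rng)
            before = fw.evaluate_kb(kb, dataset).accuracy
            out = fw.simplify_rules(kb, dataset)
            assert fw.evaluate_kb(out, dataset).accuracy >= before
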