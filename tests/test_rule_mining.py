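import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_transactions, random_transactions
from snprulemine.itemset_encoding import Item
from snprulemine.rule_mining import (
    MiningConfig,
    apriori_frequent_itemsets,
    brute_force_rules,
    generate_rules,
    mine_rules,
    rule_metrics_from_counts,
)

Y = Item("y", "1")


class TestRuleMetrics:
    def test_reported_cluster_counts(self):
        # the strongest reported genotype-cluster rule: 57 of 61 pattern
        # carriers are allergic, in a cohort of 308 cases / 205 controls
        m = rule_metrics_from_counts(57, 61, 308, 513)
        assert m.confidence == pytest.approx(0.934, abs=5e-4)
        assert m.support == pytest.approx(0.111, abs=5e-4)
        assert m.lift == pytest.approx(1.556, abs=5e-4)
        assert m.conviction == pytest.approx(6.094, abs=5e-4)

    def test_exception_free_rule_has_infinite_conviction(self):
        m = rule_metrics_from_counts(10, 10, 20, 20)
        assert m.confidence == 1.0
        assert m.lift == pytest.approx(1.0)
        assert math.isinf(m.conviction)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            rule_metrics_from_counts(10, 5, 20, 30)

    def test_absent_consequent_rejected(self):
        with pytest.raises(ValueError, match="lift"):
            rule_metrics_from_counts(0, 5, 0, 30)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 500), st.integers(0, 500), st.integers(1, 500),
           st.integers(1, 500))
    def test_metric_ranges_and_identities(self, m_extra, n_xy, dx, dy):
        # construct always-consistent counts: n_xy <= n_x, n_y <= m
        n_x, n_y = n_xy + dx, n_xy + dy
        m = max(n_x, n_y) + m_extra
        r = rule_metrics_from_counts(n_xy, n_x, n_y, m)
        assert 0 <= r.support <= r.confidence <= 1
        assert r.lift == pytest.approx(r.confidence * m / n_y, rel=1e-12)
        assert r.conviction >= 0


class TestApriori:
    def test_toy_enumeration(self):
        A, B, C = Item("A", "1"), Item("B", "1"), Item("C", "1")
        transactions = make_transactions([
            [("A", "1"), ("B", "1")], [("A", "1"), ("B", "1")], [("A", "1"), ("C", "1")],
        ])
        freq = {frozenset(f.items): f.support
                for f in apriori_frequent_itemsets(transactions, 0.6)}
        assert freq == {
            frozenset({A}): pytest.approx(1.0),
            frozenset({B}): pytest.approx(2 / 3),
            frozenset({A, B}): pytest.approx(2 / 3),
        }

    def test_full_support_threshold(self):
        transactions = make_transactions([
            [("A", "1"), ("B", "1")], [("A", "1")], [("A", "1"), ("B", "1")],
        ])
        freq = apriori_frequent_itemsets(transactions, 1.0)
        assert [set(f.items) for f in freq] == [{Item("A", "1")}]

    def test_zero_support_refused(self):
        with pytest.raises(ValueError):
            apriori_frequent_itemsets(make_transactions([[("A", "1")]]), 0.0)

    def test_antimonotonicity_over_mined_itemsets(self):
        rng = np.random.default_rng(11)
        transactions = random_transactions(rng, n_transactions=80, n_features=6)
        freq = apriori_frequent_itemsets(transactions, 0.1)
        support = {f.items: f.support for f in freq}
        for f in freq:
            for k in range(1, len(f.items)):
                for sub in combinations(sorted(f.items), k):
                    assert support[frozenset(sub)] >= f.support

    def test_max_len_bounds_itemset_size(self):
        rng = np.random.default_rng(3)
        transactions = random_transactions(rng)
        freq = apriori_frequent_itemsets(transactions, 0.1, max_len=2)
        assert max(len(f.items) for f in freq) <= 2


class TestGenerateRules:
    def test_toy_rule_kept_at_exact_confidence(self):
        # 9 of 10 g1-transactions contain y: confidence exactly 0.9
        rows = [[("g1", "1"), ("y", "1")]] * 9 + [[("g1", "1"), ("y", "0")]]
        transactions = make_transactions(rows)
        cfg = MiningConfig(min_support=0.5, min_confidence=0.9, consequent=Y)
        rules = mine_rules(transactions, cfg)
        assert len(rules) == 1
        assert rules[0].antecedent == frozenset({Item("g1", "1")})
        assert rules[0].metrics.confidence == pytest.approx(0.9)

    def test_threshold_is_inclusive_not_exclusive(self):
        rows = [[("g1", "1"), ("y", "1")]] * 9 + [[("g1", "1"), ("y", "0")]]
        transactions = make_transactions(rows)
        kept = mine_rules(transactions, MiningConfig(0.5, 0.9, Y))
        dropped = mine_rules(transactions, MiningConfig(0.5, 0.9 + 1e-9, Y))
        assert len(kept) == 1 and len(dropped) == 0

    def test_absent_consequent_yields_no_rules(self):
        transactions = make_transactions([[("A", "1")], [("A", "1"), ("B", "1")]])
        assert mine_rules(transactions, MiningConfig(0.5, 0.5, Y)) == []

    def test_max_antecedent_len_one(self):
        rng = np.random.default_rng(5)
        transactions = random_transactions(rng)
        cfg = MiningConfig(0.1, 0.5, Y, max_antecedent_len=1)
        for rule in mine_rules(transactions, cfg):
            assert len(rule.antecedent) == 1

    def test_metric_identities_hold_for_every_rule(self):
        rng = np.random.default_rng(8)
        transactions = random_transactions(rng, n_transactions=120)
        for rule in mine_rules(transactions, MiningConfig(0.05, 0.3, Y)):
            m = rule.metrics
            p_y = m.n_y / m.m
            assert m.lift == pytest.approx(m.confidence / p_y, rel=1e-12)
            if m.confidence < 1.0:
                assert m.conviction == pytest.approx(
                    (1 - p_y) / (1 - m.confidence), rel=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_apriori_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        transactions = random_transactions(rng, n_transactions=n,
                                           n_features=int(rng.integers(4, 9)))
        cfg = MiningConfig(min_support=0.1, min_confidence=0.6, consequent=Y)
        mined = mine_rules(transactions, cfg)
        oracle = brute_force_rules(transactions, cfg)
        assert [(r.antecedent, r.metrics) for r in mined] == \
               [(r.antecedent, r.metrics) for r in oracle]

    def test_oracle_refuses_large_catalogs(self):
        rows = [[(f"f{i}", "1") for i in range(26)]]
        with pytest.raises(ValueError, match="25-item"):
            brute_force_rules(make_transactions(rows), MiningConfig(0.1, 0.5, Y))

    def test_oracle_empty_transactions(self):
        assert brute_force_rules([], MiningConfig(0.1, 0.5, Y)) == []


def test_rule_ordering_deterministic():
    rng = np.random.default_rng(42)
    transactions = random_transactions(rng, n_transactions=100)
    cfg = MiningConfig(0.05, 0.3, Y)
    rules = mine_rules(transactions, cfg)
    keys = [(-r.metrics.confidence, -r.metrics.support, r.antecedent_sorted)
            for r in rules]
    assert keys == sorted(keys)
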