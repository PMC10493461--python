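import math

import numpy as np
import pytest

from fctf import (
    build_transactions,
    derive_rules,
    filter_rules,
    item_role_frequencies,
    mine_frequent_itemsets,
)
from fctf.arm import AssociationRule, RuleThresholds, Transaction, TransactionSet, write_rules
from fctf.errors import ParameterError, ValidationError
from fctf.synthetic import enumerate_itemsets_bruteforce, enumerate_rules_bruteforce
from conftest import random_transaction_set


def rule_key(rule):
    return tuple(sorted(rule.antecedent)), tuple(sorted(rule.consequent))


# ---------------------------------------------------------------------------
# Transaction construction
# ---------------------------------------------------------------------------

def test_transactions_one_per_component_and_disease(demo, demo_tx):
    assert demo_tx.N == 4
    assert build_transactions(demo.predictions, demo.functions, mode="components").N == 3
    assert build_transactions(demo.predictions, demo.functions, mode="functions").N == 1


def test_transactions_fall_back_when_functions_empty(demo):
    tx = build_transactions(demo.predictions, [], mode="both")
    assert tx.N == 3 and all(t.origin == "component" for t in tx.transactions)
    with pytest.raises(ValidationError):
        build_transactions([], [], mode="both")
    with pytest.raises(ParameterError):
        build_transactions(demo.predictions, demo.functions, mode="bogus")


def test_occurrence_counts_are_monotone_in_itemset_size(demo_tx):
    # P(S) >= P(S') whenever S is a subset of S'; P(empty) = N
    assert demo_tx.count([]) == demo_tx.N
    for s, s_prime in [(["A"], ["A", "B"]), (["B"], ["A", "B", "C"]), ([], ["C"])]:
        assert demo_tx.count(s) >= demo_tx.count(s_prime)


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------

def test_demo_frequent_itemsets_exact(demo_tx):
    itemsets = dict(mine_frequent_itemsets(demo_tx, 0.2, 2))
    assert itemsets == {
        frozenset("A"): 0.75, frozenset("B"): 0.75, frozenset("C"): 0.5,
        frozenset("AB"): 0.5, frozenset("BC"): 0.5, frozenset("AC"): 0.25,
    }


def test_high_support_threshold_yields_nothing(demo_tx):
    assert mine_frequent_itemsets(demo_tx, 0.9, 2) == []


def test_single_transaction_trivial_case():
    tx = TransactionSet([Transaction("t", "component", frozenset("A"))])
    assert mine_frequent_itemsets(tx, 0.5, 2) == [(frozenset("A"), 1.0)]


def test_mining_parameter_errors(demo_tx):
    with pytest.raises(ParameterError):
        mine_frequent_itemsets(demo_tx, 0.2, 0)
    with pytest.raises(ParameterError):
        mine_frequent_itemsets(demo_tx, 0.0, 2)


def test_percent_thresholds_normalise_to_fractions(demo_tx):
    assert mine_frequent_itemsets(demo_tx, 20, 2) == mine_frequent_itemsets(demo_tx, 0.2, 2)
    assert RuleThresholds(min_support=20, min_confidence=35).min_support == 0.20


def test_downward_closure_on_random_databases():
    rng = np.random.default_rng(11)
    for _ in range(10):
        tx = random_transaction_set(rng)
        frequent = {s for s, _ in mine_frequent_itemsets(tx, 0.15, 3)}
        for itemset in frequent:
            for item in itemset:
                if len(itemset) > 1:
                    assert itemset - {item} in frequent


# ---------------------------------------------------------------------------
# Rule derivation
# ---------------------------------------------------------------------------

def test_demo_rules_match_bundled_hand_values(demo, demo_tx):
    itemsets = mine_frequent_itemsets(demo_tx, 0.2, 2)
    rules = derive_rules(itemsets, demo_tx)
    computed = {
        rule_key(r): (r.support, r.confidence, r.lift, r.leverage, r.conviction)
        for r in rules
    }
    reference = {
        (tuple([a]), tuple([b])): v for (a, b), v in demo.reference_rules.items()
    }
    assert computed == reference  # float-for-float identical


def test_confidence_one_gives_infinite_conviction(demo_tx):
    rules = derive_rules(mine_frequent_itemsets(demo_tx, 0.2, 2), demo_tx)
    c_to_b = next(r for r in rules if rule_key(r) == (("C",), ("B",)))
    assert c_to_b.confidence == 1.0 and math.isinf(c_to_b.conviction)


def test_rules_never_overlap_antecedent_and_consequent():
    rng = np.random.default_rng(5)
    tx = random_transaction_set(rng)
    for rule in derive_rules(mine_frequent_itemsets(tx, 0.1, 3), tx):
        assert rule.antecedent and rule.consequent
        assert not rule.antecedent & rule.consequent


def test_derive_rules_rejects_foreign_itemsets(demo_tx):
    with pytest.raises(ValidationError):
        derive_rules([(frozenset(["ZZZ", "QQQ"]), 0.5)], demo_tx)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def test_default_filter_keeps_only_positive_dependence(demo_tx):
    rules = derive_rules(mine_frequent_itemsets(demo_tx, 0.2, 2), demo_tx)
    kept = filter_rules(rules)
    assert [rule_key(r) for r in kept] == [(("C",), ("B",)), (("B",), ("C",))]
    # A -> B has lift 8/9 < 1 and is dropped


def test_filter_boundaries_are_strict():
    rule = AssociationRule(frozenset("A"), frozenset("B"), 0.5, 0.5, 1.0, 0.1, 2.0)
    assert filter_rules([rule], RuleThresholds(0, 0, 1.0, -1, -1)) == []
    passing = AssociationRule(frozenset("A"), frozenset("B"), 0.5, 0.5, 1.0001, 0.1, 2.0)
    assert filter_rules([passing], RuleThresholds(0, 0, 1.0, -1, -1)) == [passing]


def test_infinite_conviction_passes_any_finite_bound():
    rule = AssociationRule(frozenset("A"), frozenset("B"), 0.5, 1.0, 2.0, 0.1, math.inf)
    assert filter_rules([rule], RuleThresholds(0, 0, 0, 0, 1e9)) == [rule]


def test_filter_output_is_deterministically_sorted():
    rng = np.random.default_rng(7)
    tx = random_transaction_set(rng)
    rules = derive_rules(mine_frequent_itemsets(tx, 0.1, 2), tx)
    a = filter_rules(rules, RuleThresholds(0.1, 0.1, 0, -1, -1))
    b = filter_rules(list(reversed(rules)), RuleThresholds(0.1, 0.1, 0, -1, -1))
    assert a == b
    keys = [(-r.support, -r.confidence, r.label) for r in a]
    assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# Role frequencies
# ---------------------------------------------------------------------------

def test_item_role_frequencies_counts_and_symmetry():
    def rule(x, y):
        return AssociationRule(frozenset([x]), frozenset([y]), 0.5, 0.5, 2, 0.1, 2)

    table = item_role_frequencies([rule("A", "B"), rule("B", "A"), rule("A", "C")])
    rows = {r.target: (r.antecedent_count, r.consequent_count) for r in table.itertuples()}
    assert rows == {"A": (2, 1), "B": (1, 1), "C": (0, 1)}

    assert item_role_frequencies([]).empty

    symmetric = [rule(x, y) for x, y in
                 [("A", "B"), ("B", "A"), ("B", "C"), ("C", "B"), ("A", "C"), ("C", "A")]]
    table = item_role_frequencies(symmetric)
    assert (table["antecedent_count"] == table["consequent_count"]).all()


# ---------------------------------------------------------------------------
# Oracle equivalence and metric identities (desk-scale versions)
# ---------------------------------------------------------------------------

def test_apriori_equals_powerset_oracle_on_random_databases():
    rng = np.random.default_rng(42)
    for _ in range(20):
        tx = random_transaction_set(rng)
        min_support = float(rng.uniform(0.05, 0.5))
        mined = dict(mine_frequent_itemsets(tx, min_support, 3))
        oracle = enumerate_itemsets_bruteforce(tx, min_support, 3)
        assert mined == oracle
        rules = {rule_key(r): (r.support, r.confidence, r.lift, r.leverage, r.conviction)
                 for r in derive_rules(list(mined.items()), tx)}
        assert rules == enumerate_rules_bruteforce(tx, min_support, 3)


def test_metric_identities_on_random_rules():
    rng = np.random.default_rng(9)
    for _ in range(10):
        tx = random_transaction_set(rng)
        rules = derive_rules(mine_frequent_itemsets(tx, 0.1, 2), tx)
        by_key = {rule_key(r): r for r in rules}
        for key, rule in by_key.items():
            reverse = by_key[(key[1], key[0])]
            assert rule.lift == pytest.approx(reverse.lift, abs=1e-9)
            assert rule.leverage == pytest.approx(reverse.leverage, abs=1e-9)
            assert rule.confidence >= rule.support - 1e-12
            if rule.lift > 1 + 1e-9:
                assert rule.leverage > 0
            if rule.leverage > 1e-9:
                assert rule.lift > 1


def test_rule_table_serialisation_round_trip(tmp_path, demo_tx):
    rules = filter_rules(derive_rules(mine_frequent_itemsets(demo_tx, 0.2, 2), demo_tx))
    path = tmp_path / "rules.tsv"
    write_rules(rules, path)
    text = path.read_text()
    assert "inf" in text  # +inf sentinel serialised
    assert text == (path.read_text())  # stable bytes
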