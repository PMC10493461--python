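import numpy as np
import pandas as pd
import pytest

from fctf.arm import AssociationRule
from fctf.errors import ClassBalanceError, ValidationError
from fctf.io import FunctionAssociation, TargetPrediction
from fctf.screening import (
    BidirectionalTarget,
    bidirectional_targets,
    build_feature_table,
    evaluate_classifiers,
    intersect_gene_sets,
    map_targets_to_components,
    read_gmt,
    read_symbol_list,
)


def P(component, target, probability=0.5):
    return TargetPrediction(component, target, probability)


def F(target, disease):
    return FunctionAssociation(target, disease, "c1")


# ---------------------------------------------------------------------------
# Bidirectional screening
# ---------------------------------------------------------------------------

def test_bidirectional_degrees_are_distinct_counts_and_strict():
    predictions = [P(f"c{i}", "T1") for i in range(3)] + [P("c0", "T1")]  # 3 distinct
    predictions += [P("c0", "T2"), P("c1", "T2")]                         # 2 distinct
    functions = [F("T1", f"d{i}") for i in range(5)] + [F("T2", "d0"), F("T2", "d1"), F("T2", "d2")]
    out = {b.target: b for b in bidirectional_targets(predictions, functions)}
    assert (out["T1"].degree_ct, out["T1"].degree_tf) == (3, 5)
    assert out["T1"].bidirectional            # 3 > 2 and 5 > 2
    assert not out["T2"].bidirectional        # degree_ct == 2 fails the strict cut


def test_bidirectional_includes_single_sided_targets_and_sorts():
    predictions = [P("c0", "T1"), P("c0", "T2")]
    functions = [F("T1", "d0"), F("T3", "d0"), F("T3", "d1")]
    out = bidirectional_targets(predictions, functions)
    assert [b.target for b in out] == ["T3", "T1", "T2"]  # tf desc, ct desc, name
    assert {b.target: b.degree_ct for b in out} == {"T3": 0, "T1": 1, "T2": 1}
    with pytest.raises(ValidationError):
        bidirectional_targets(predictions, [])


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def targets_fixture(n_pos=4, n_neg=6):
    out = []
    for i in range(n_pos):
        out.append(BidirectionalTarget(f"P{i}", 3 + i, 4 + i, True))
    for i in range(n_neg):
        out.append(BidirectionalTarget(f"N{i}", 1, 1, False))
    return out


def test_feature_table_shape_labels_and_rule_features():
    rules = [AssociationRule(frozenset(["P0"]), frozenset(["P1"]), 0.4, 0.8, 2.0, 0.1, 2.0)]
    features, labels = build_feature_table(targets_fixture(), rules)
    assert features.shape == (10, 6)
    assert labels.sum() == 4
    assert features.loc["P0", "antecedent_count"] == 1
    assert features.loc["P0", "max_rule_support"] == 0.4
    assert features.loc["N0", "max_rule_confidence"] == 0.0  # absent from all rules
    dropped, _ = build_feature_table(targets_fixture(), rules, drop_degree_features=True)
    assert "degree_ct" not in dropped.columns


def test_feature_table_is_row_order_invariant():
    targets = targets_fixture()
    a, la = build_feature_table(targets, [])
    b, lb = build_feature_table(list(reversed(targets)), [])
    pd.testing.assert_frame_equal(a, b)
    assert (la == lb).all()


def test_feature_table_class_imbalance_error():
    with pytest.raises(ClassBalanceError):
        build_feature_table(targets_fixture(n_pos=1, n_neg=9), [])


# ---------------------------------------------------------------------------
# Classifier evaluation
# ---------------------------------------------------------------------------

def separable_features(n=60, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 2) + [0] * (n // 2))
    signal = np.where(labels == 1, rng.uniform(0.5, 1.5, n), rng.uniform(-1.5, -0.5, n))
    noise = rng.normal(size=(n, 2))
    features = pd.DataFrame(
        {"signal": signal, "noise_a": noise[:, 0], "noise_b": noise[:, 1]},
        index=[f"t{i}" for i in range(n)],
    )
    return features, labels


def test_separable_fixture_reaches_perfect_auc():
    features, labels = separable_features()
    reports = evaluate_classifiers(features, labels, seed=3, folds=5)
    assert {r.model for r in reports} == {"random_forest", "svm_rbf"}
    for report in reports:
        assert report.auc == 1.0


def test_roc_invariants_and_importances():
    features, labels = separable_features()
    forest, svm = evaluate_classifiers(features, labels, seed=3, folds=5)
    for report in (forest, svm):
        fpr = [f for f, _ in report.roc_points]
        assert report.roc_points[0] == (0.0, 0.0)
        assert report.roc_points[-1] == (1.0, 1.0)
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
    assert svm.importances is None
    assert sum(forest.importances.values()) == pytest.approx(1.0, abs=1e-9)
    assert max(forest.importances, key=forest.importances.get) == "signal"


def test_reports_are_byte_identical_under_fixed_seed():
    features, labels = separable_features()
    first = evaluate_classifiers(features, labels, seed=11, folds=4)
    second = evaluate_classifiers(features, labels, seed=11, folds=4)
    assert [r.to_json() for r in first] == [r.to_json() for r in second]


def test_classifier_error_and_fold_reduction():
    features, labels = separable_features(n=12)
    with pytest.raises(ClassBalanceError):
        evaluate_classifiers(features, np.ones_like(labels), seed=0)
    reports = evaluate_classifiers(features, labels, seed=0, folds=50)  # folds reduced
    assert all(("6-fold" in r.cv_scheme) for r in reports)


# ---------------------------------------------------------------------------
# Gene-set intersection and back-mapping
# ---------------------------------------------------------------------------

def test_gmt_and_symbol_list_parsing(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("digestive\tdesc\tace\tPTGS2\tCYP2C19\nneuro\tdesc\tACE\tDRD2\n")
    sets = read_gmt(gmt)
    assert sets == {"digestive": {"ACE", "PTGS2", "CYP2C19"}, "neuro": {"ACE", "DRD2"}}

    txt = tmp_path / "genes.txt"
    txt.write_text("ace\nptgs2\n\n")
    assert read_symbol_list(txt) == {"ACE", "PTGS2"}


def test_intersection_core_and_invariance():
    targets = ["A", "B", "C"]
    sets = {"s1": {"B", "C"}, "s2": {"C", "D"}}
    result, core = intersect_gene_sets(targets, sets)
    assert core == ["C"]
    assert result.count("targets") == 1        # A only
    assert result.count("s2") == 1             # D only
    # duplication/order invariance; core contained in every input set
    _, core2 = intersect_gene_sets(["C", "B", "A", "A"], sets)
    assert core2 == core
    for members in sets.values():
        assert set(core) <= members


def test_intersection_disjoint_set_empties_core():
    _, core = intersect_gene_sets(["A"], {"s1": {"B"}})
    assert core == []


def test_back_mapping_orders_components_by_probability():
    predictions = [P("citronellal", "ACE", 0.3), P("geraniol", "ACE", 0.6)]
    key_map = map_targets_to_components(["ACE"], predictions,
                                        gene_sets={"digestive": {"ACE"}})
    entry = key_map.entries[0]
    assert entry.components == ["geraniol", "citronellal"]
    assert entry.best_probability["geraniol"] == 0.6
    assert entry.gene_sets == ["digestive"]


def test_back_mapping_handles_target_without_predictions():
    key_map = map_targets_to_components(["ACE"], [P("x", "OTHER", 0.9)])
    assert key_map.entries[0].components == []
    with pytest.raises(ValidationError):
        map_targets_to_components([], [])
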