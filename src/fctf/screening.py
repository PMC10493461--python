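"""Bidirectional-target screening, classifier evaluation and back-mapping.

A *bidirectional* target is associated with more than ``min_ct`` components
and more than ``min_tf`` diseases (strict, defaults 2 and 2, i.e. at least
three of each) — it carries evidence on both sides of the
component-target-function chain.  Separability of the bidirectional class
is probed with a random-forest and an RBF-SVM classifier over simple
degree- and rule-derived features, scored by pooled cross-validated ROC/AUC.
Because the degree features encode the screening rule itself, near-perfect
AUC is expected unless ``drop_degree_features`` is set; the flag exists as a
leakage check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .arm import AssociationRule
from .errors import ClassBalanceError, ValidationError
from .io import FunctionAssociation, TargetPrediction, normalize_symbol
from .network import VennResult, venn

logger = logging.getLogger("fctf.screening")

FEATURE_COLUMNS = (
    "degree_ct",
    "degree_tf",
    "antecedent_count",
    "consequent_count",
    "max_rule_support",
    "max_rule_confidence",
)
DEGREE_FEATURES = ("degree_ct", "degree_tf")


@dataclass(frozen=True)
class BidirectionalTarget:
    target: str
    degree_ct: int
    degree_tf: int
    bidirectional: bool


@dataclass
class ModelReport:
    """Cross-validated ROC evaluation of one classifier."""

    model: str
    auc: float
    roc_points: list[tuple[float, float]]
    seed: int
    cv_scheme: str
    importances: dict[str, float] | None = None

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "auc": self.auc,
            "roc_points": [[float(f), float(t)] for f, t in self.roc_points],
            "seed": self.seed,
            "cv_scheme": self.cv_scheme,
            "importances": self.importances,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class KeyTargetEntry:
    target: str
    gene_sets: list[str]
    components: list[str]
    best_probability: dict[str, float]


@dataclass
class KeyTargetMap:
    entries: list[KeyTargetEntry] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            e.target: {
                "gene_sets": e.gene_sets,
                "components": e.components,
                "best_probability": e.best_probability,
            }
            for e in self.entries
        }


# ---------------------------------------------------------------------------
# Bidirectional screening
# ---------------------------------------------------------------------------

def bidirectional_targets(
    predictions: Sequence[TargetPrediction],
    functions: Sequence[FunctionAssociation],
    min_ct: int = 2,
    min_tf: int = 2,
) -> list[BidirectionalTarget]:
    """Distinct-count degrees per target; bidirectional iff both exceed cuts.

    Sorted by disease degree desc, then component degree desc, then symbol.
    """
    if not predictions or not functions:
        raise ValidationError("bidirectional screening needs both predictions and functions")
    ct: dict[str, set[str]] = {}
    tf: dict[str, set[str]] = {}
    for p in predictions:
        ct.setdefault(p.target, set()).add(p.component)
    for a in functions:
        tf.setdefault(a.target, set()).add(a.disease)
    out = []
    for target in set(ct) | set(tf):
        degree_ct = len(ct.get(target, ()))
        degree_tf = len(tf.get(target, ()))
        out.append(
            BidirectionalTarget(
                target=target,
                degree_ct=degree_ct,
                degree_tf=degree_tf,
                bidirectional=degree_ct > min_ct and degree_tf > min_tf,
            )
        )
    out.sort(key=lambda b: (-b.degree_tf, -b.degree_ct, b.target))
    logger.info(
        "bidirectional screen (> %d components, > %d diseases): %d of %d targets",
        min_ct, min_tf, sum(b.bidirectional for b in out), len(out),
    )
    return out


def build_feature_table(
    targets: Sequence[BidirectionalTarget],
    rules: Sequence[AssociationRule] = (),
    drop_degree_features: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-target feature grid and binary bidirectional labels.

    Features: the two degrees plus rule-derived counts and the strongest
    support/confidence of any rule mentioning the target (0 when absent
    from all rules).  ``drop_degree_features`` removes the two degree
    columns, which otherwise encode the label rule (leakage check).
    """
    ante: dict[str, int] = {}
    cons: dict[str, int] = {}
    best_support: dict[str, float] = {}
    best_confidence: dict[str, float] = {}
    for rule in rules:
        for item in rule.antecedent:
            ante[item] = ante.get(item, 0) + 1
        for item in rule.consequent:
            cons[item] = cons.get(item, 0) + 1
        for item in rule.antecedent | rule.consequent:
            best_support[item] = max(best_support.get(item, 0.0), rule.support)
            best_confidence[item] = max(best_confidence.get(item, 0.0), rule.confidence)

    rows = []
    for b in sorted(targets, key=lambda t: t.target):
        rows.append(
            {
                "target": b.target,
                "degree_ct": b.degree_ct,
                "degree_tf": b.degree_tf,
                "antecedent_count": ante.get(b.target, 0),
                "consequent_count": cons.get(b.target, 0),
                "max_rule_support": best_support.get(b.target, 0.0),
                "max_rule_confidence": best_confidence.get(b.target, 0.0),
                "label": int(b.bidirectional),
            }
        )
    frame = pd.DataFrame(rows).set_index("target")
    labels = frame.pop("label").to_numpy()
    if drop_degree_features:
        frame = frame.drop(columns=list(DEGREE_FEATURES))
    if min(np.sum(labels == 1), np.sum(labels == 0)) < 2:
        raise ClassBalanceError(
            "need at least 2 targets in each class to evaluate classifiers"
        )
    return frame, labels


# ---------------------------------------------------------------------------
# Classifier evaluation
# ---------------------------------------------------------------------------

def evaluate_classifiers(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int,
    folds: int = 5,
) -> list[ModelReport]:
    """Pooled cross-validated ROC/AUC for a random forest and an RBF SVM.

    Out-of-fold probability scores from a stratified K-fold split are
    concatenated into a single ROC per model.  Impurity (Gini) feature
    importances come from the forest refit on all rows.  Fully reproducible
    for a fixed seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ClassBalanceError("labels contain a single class")
    if folds < 2:
        raise ClassBalanceError("need at least 2 folds")
    usable = int(counts.min())
    if usable < folds:
        logger.warning("reducing folds from %d to %d (smallest class size)", folds, usable)
        folds = usable

    x = features.to_numpy(dtype=float)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    def pooled_scores(make_model):
        # ROC needs only a monotone score: class-1 probability for the
        # forest, signed margin distance for the SVM.
        scores = np.empty(len(labels))
        for train, test in splitter.split(x, labels):
            model = make_model()
            model.fit(x[train], labels[train])
            if hasattr(model, "predict_proba"):
                scores[test] = model.predict_proba(x[test])[:, 1]
            else:
                scores[test] = model.decision_function(x[test])
        return scores

    reports = []
    cv_scheme = f"stratified {folds}-fold, pooled out-of-fold scores"

    forest_scores = pooled_scores(
        lambda: RandomForestClassifier(n_estimators=200, random_state=seed)
    )
    fpr, tpr, _ = roc_curve(labels, forest_scores)
    full_forest = RandomForestClassifier(n_estimators=200, random_state=seed).fit(x, labels)
    importances = {
        name: float(v) for name, v in zip(features.columns, full_forest.feature_importances_)
    }
    reports.append(
        ModelReport(
            model="random_forest",
            auc=float(sk_auc(fpr, tpr)),
            roc_points=list(zip(map(float, fpr), map(float, tpr))),
            seed=seed,
            cv_scheme=cv_scheme,
            importances=importances,
        )
    )

    svm_scores = pooled_scores(
        lambda: make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    )
    fpr, tpr, _ = roc_curve(labels, svm_scores)
    reports.append(
        ModelReport(
            model="svm_rbf",
            auc=float(sk_auc(fpr, tpr)),
            roc_points=list(zip(map(float, fpr), map(float, tpr))),
            seed=seed,
            cv_scheme=cv_scheme,
        )
    )
    for report in reports:
        logger.info("%s AUC = %.3f", report.model, report.auc)
    return reports


# ---------------------------------------------------------------------------
# Gene-set intersection and back-mapping
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member symbols."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line with fewer than 3 fields: {line!r}")
        sets[parts[0]] = {normalize_symbol(s) for s in parts[2:] if s.strip()}
    return sets


def read_symbol_list(path: str | Path) -> set[str]:
    """One gene symbol per line."""
    return {
        normalize_symbol(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def intersect_gene_sets(
    targets: Sequence[str],
    gene_sets: Mapping[str, set[str]],
) -> tuple[VennResult, list[str]]:
    """Venn regions over {targets} and the named sets; core = in all of them."""
    if not gene_sets:
        raise ValidationError("need at least one named gene set")
    named = {"targets": {normalize_symbol(t) for t in targets}}
    for name, members in gene_sets.items():
        if not members:
            logger.warning("gene set %r is empty (kept)", name)
        named[name] = {normalize_symbol(s) for s in members}
    result = venn(named)
    core = set(named["targets"])
    for name in gene_sets:
        core &= named[name]
    return result, sorted(core)


def map_targets_to_components(
    core: Sequence[str],
    predictions: Sequence[TargetPrediction],
    gene_sets: Mapping[str, set[str]] | None = None,
) -> KeyTargetMap:
    """For each key target, its predicted components sorted by probability."""
    if not core:
        raise ValidationError("no key targets to back-map")
    by_target: dict[str, dict[str, float]] = {}
    for p in predictions:
        best = by_target.setdefault(p.target, {})
        if p.probability > best.get(p.component, -1.0):
            best[p.component] = p.probability
    entries = []
    for symbol in core:
        symbol = normalize_symbol(symbol)
        hits = by_target.get(symbol, {})
        if not hits:
            logger.warning("key target %s has no prediction edge", symbol)
        components = sorted(hits, key=lambda c: (-hits[c], c))
        containing = (
            sorted(n for n, members in gene_sets.items() if symbol in members)
            if gene_sets
            else []
        )
        entries.append(
            KeyTargetEntry(
                target=symbol,
                gene_sets=containing,
                components=components,
                best_probability={c: hits[c] for c in components},
            )
        )
    return KeyTargetMap(entries=entries)
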