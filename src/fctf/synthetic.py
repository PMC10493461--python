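"""Synthetic component-target-function dataset generation.

Emulates the shape of a real medicinal-food snapshot without any download:
a component library whose relative contents follow a skewed log-normal
profile (a few dominant components, many trace ones) measured under two
detection methods; a sparse component->target bipartite map with per-edge
probabilities; and a target->disease map with round-robin disease
categories so every category is populated.  Optionally, "planted" target
pairs receive boosted co-occurrence: any index entity containing one member
of a planted pair gains the other with the given boost probability, which
creates a high-co-occurrence signal the mining pipeline should recover.

Everything is driven by a single integer seed through one generator, so an
identical spec always yields an identical dataset.

The module also carries the fixed hand-checkable micro fixture
(:func:`worked_example`, "demo4": three components and one disease over
items A, B, C giving four transactions) together with an exhaustive
power-set rule enumerator that is deliberately independent of the Apriori
implementation — it recounts occurrences by scanning transactions directly
and serves as the oracle the mining code is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .arm import Transaction, TransactionSet
from .errors import GenerationError, ParameterError
from .io import (
    CHEMICAL_CATEGORIES,
    ComponentRecord,
    FunctionAssociation,
    TargetPrediction,
)

DETECTION_METHODS = ("m1", "m2")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults give 30 components and 20 diseases (50 index entities) over
    15 targets at edge density 0.25 — a desk-scale snapshot in which a
    planted pair is recoverable but random pairs rarely pass the default
    rule thresholds.
    """

    n_components: int = 30
    n_targets: int = 15
    n_diseases: int = 20
    n_categories: int = 5
    content_mu: float = 0.0
    content_sigma: float = 1.5
    edge_density_ct: float = 0.25
    edge_density_tf: float = 0.25
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def target_names(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_targets + 1)]

    def validate(self) -> None:
        if self.n_components < 0 or self.n_targets < 1 or self.n_diseases < 0:
            raise ParameterError("counts must be non-negative (targets >= 1)")
        for density in (self.edge_density_ct, self.edge_density_tf):
            if not 0 < density <= 1:
                raise ParameterError(f"edge density must be in (0, 1], got {density}")
        universe = set(self.target_names())
        for x, y, boost in self.planted_pairs:
            if x not in universe or y not in universe:
                raise ParameterError(f"planted pair ({x}, {y}) outside target universe")
            if not 0 <= boost <= 1:
                raise ParameterError(f"boost probability {boost} outside [0, 1]")


@dataclass
class DatasetBundle:
    components: list[ComponentRecord]
    predictions: list[TargetPrediction]
    functions: list[FunctionAssociation]


def generate(spec: SyntheticSpec) -> DatasetBundle:
    """Draw one dataset from the spec, deterministically in the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    targets = spec.target_names()
    components = []
    for i in range(spec.n_components):
        name = f"c{i + 1:03d}"
        category = CHEMICAL_CATEGORIES[i % len(CHEMICAL_CATEGORIES)]
        contents = {
            m: float(rng.lognormal(spec.content_mu, spec.content_sigma))
            for m in DETECTION_METHODS
        }
        components.append(ComponentRecord(name=name, category=category, contents=contents))

    ct_sets: dict[str, set[str]] = {}
    for component in components:
        hits = {t for t in targets if rng.random() < spec.edge_density_ct}
        ct_sets[component.name] = hits

    tf_sets: dict[str, set[str]] = {}
    categories = [f"category_{k + 1}" for k in range(spec.n_categories)]
    disease_category = {}
    for k in range(spec.n_diseases):
        disease = f"disease_{k + 1:03d}"
        disease_category[disease] = categories[k % len(categories)] if categories else "unknown"
        tf_sets[disease] = {t for t in targets if rng.random() < spec.edge_density_tf}

    # Planted co-occurrence: an index entity containing either member of a
    # pair gains the other with probability `boost` (applied to components
    # first, then diseases, in pair order — fixed for determinism).
    for x, y, boost in spec.planted_pairs:
        for sets in (ct_sets, tf_sets):
            for entity in sets:
                members = sets[entity]
                has_x, has_y = x in members, y in members
                if has_x and not has_y and rng.random() < boost:
                    members.add(y)
                elif has_y and not has_x and rng.random() < boost:
                    members.add(x)

    predictions = [
        TargetPrediction(component=c, target=t, probability=float(1.0 - rng.random()))
        for c in sorted(ct_sets)
        for t in sorted(ct_sets[c])
    ]
    functions = [
        FunctionAssociation(
            target=t, disease=d, category=disease_category[d], source="synthetic"
        )
        for d in sorted(tf_sets)
        for t in sorted(tf_sets[d])
    ]
    if not predictions and not functions:
        raise GenerationError("spec produced no transactions (all target sets empty)")
    return DatasetBundle(components, predictions, functions)


def null_dataset(spec: SyntheticSpec) -> DatasetBundle:
    """Independent-edge dataset (no planted pairs) for null calibration."""
    if spec.planted_pairs:
        raise ParameterError("null dataset must not contain planted pairs")
    return generate(spec)


# ---------------------------------------------------------------------------
# Fixed worked example ("demo4")
# ---------------------------------------------------------------------------

#: Hand-computed reference metrics for every rule derivable from the demo4
#: frequent pairs at support > 0.2: (support, confidence, lift, leverage,
#: conviction).  Counts over the four transactions {A,B},{A,B,C},{A},{B,C}:
#: P(A)=3, P(B)=3, P(C)=2, P(AB)=2, P(BC)=2, P(AC)=1.
#: Each value is written as the exact arithmetic of the defining formula so
#: the comparison with computed rules is float-for-float identical (e.g.
#: conviction(A->B) = (1 - 3/4) / (1 - 2/3) ~= 0.75).
DEMO4_REFERENCE = {
    ("A", "B"): (0.5, 2 / 3, (2 / 3) / (3 / 4), 0.5 - (3 / 4) * (3 / 4), (1 - 3 / 4) / (1 - 2 / 3)),
    ("B", "A"): (0.5, 2 / 3, (2 / 3) / (3 / 4), 0.5 - (3 / 4) * (3 / 4), (1 - 3 / 4) / (1 - 2 / 3)),
    ("B", "C"): (0.5, 2 / 3, (2 / 3) / (2 / 4), 0.5 - (3 / 4) * (2 / 4), (1 - 2 / 4) / (1 - 2 / 3)),
    ("C", "B"): (0.5, 1.0, 1.0 / (3 / 4), 0.5 - (2 / 4) * (3 / 4), math.inf),
    ("A", "C"): (0.25, 1 / 3, (1 / 3) / (2 / 4), 0.25 - (3 / 4) * (2 / 4), (1 - 2 / 4) / (1 - 1 / 3)),
    ("C", "A"): (0.25, 1 / 2, (1 / 2) / (3 / 4), 0.25 - (2 / 4) * (3 / 4), (1 - 3 / 4) / (1 - 1 / 2)),
}


@dataclass
class WorkedExample(DatasetBundle):
    """demo4: 3 components + 1 disease over items A, B, C (N = 4)."""

    reference_rules: dict[tuple[str, str], tuple[float, float, float, float, float]] = field(
        default_factory=dict
    )


def worked_example() -> WorkedExample:
    """The fixed hand-computable fixture used throughout the test suite."""
    membership = {"c1": ["A", "B"], "c2": ["A", "B", "C"], "c3": ["A"]}
    components = [
        ComponentRecord(name=n, category="other", contents={m: 2.0 for m in DETECTION_METHODS})
        for n in membership
    ]
    predictions = [
        TargetPrediction(component=c, target=t, probability=0.5)
        for c, ts in membership.items()
        for t in ts
    ]
    functions = [
        FunctionAssociation(target=t, disease="f1", category="category_1", source="demo")
        for t in ["B", "C"]
    ]
    return WorkedExample(
        components=components,
        predictions=predictions,
        functions=functions,
        reference_rules=dict(DEMO4_REFERENCE),
    )


# ---------------------------------------------------------------------------
# Exhaustive power-set oracle (independent of the Apriori path)
# ---------------------------------------------------------------------------

def enumerate_itemsets_bruteforce(
    tx: TransactionSet | Sequence[Transaction],
    min_support: float,
    max_size: int,
) -> dict[frozenset[str], float]:
    """All itemsets of size <= max_size with support > min_support, by
    scanning every transaction for every candidate subset (no pruning)."""
    transactions = tx.transactions if isinstance(tx, TransactionSet) else list(tx)
    n = len(transactions)
    if n == 0:
        raise GenerationError("no transactions to enumerate")
    items = sorted(set().union(*(t.items for t in transactions)))
    out: dict[frozenset[str], float] = {}
    for size in range(1, max_size + 1):
        for candidate in combinations(items, size):
            key = frozenset(candidate)
            count = sum(1 for t in transactions if key <= t.items)
            support = count / n
            if support > min_support:
                out[key] = support
    return out


def enumerate_rules_bruteforce(
    tx: TransactionSet | Sequence[Transaction],
    min_support: float = 0.0,
    max_size: int = 2,
) -> dict[tuple[tuple[str, ...], tuple[str, ...]], tuple[float, float, float, float, float]]:
    """Direct evaluation of the five measures for every rule from every
    frequent itemset, recounting occurrences from raw transactions."""
    transactions = tx.transactions if isinstance(tx, TransactionSet) else list(tx)
    n = len(transactions)
    frequent = enumerate_itemsets_bruteforce(transactions, min_support, max_size)

    def count(key: frozenset[str]) -> int:
        return sum(1 for t in transactions if key <= t.items)

    rules = {}
    for itemset in frequent:
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        for r in range(1, len(members)):
            for ante in combinations(members, r):
                tx_set = frozenset(ante)
                ty_set = itemset - tx_set
                p_union = count(itemset)
                p_x = count(tx_set)
                p_y = count(ty_set)
                support = p_union / n
                confidence = p_union / p_x
                lift = confidence / (p_y / n)
                leverage = support - (p_x / n) * (p_y / n)
                conviction = (
                    math.inf if p_union == p_x else (1 - p_y / n) / (1 - confidence)
                )
                rules[(tuple(sorted(tx_set)), tuple(sorted(ty_set)))] = (
                    support, confidence, lift, leverage, conviction,
                )
    return rules
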