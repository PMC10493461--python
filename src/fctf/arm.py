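"""Association-rule mining over target sets (the FCTF core).

Each index entity — a chemical component or a disease — contributes one
transaction: the set of target gene symbols associated with it.  Frequent
target itemsets are found by level-wise Apriori with candidate pruning, and
every ordered partition of a frequent itemset into disjoint antecedent and
consequent yields a rule Tx -> Ty scored by five measures computed from
exact occurrence counts over the N transactions:

    support(Tx -> Ty)    = P(Tx u Ty) / N
    confidence(Tx -> Ty) = P(Tx u Ty) / P(Tx)
    lift(Tx -> Ty)       = confidence(Tx -> Ty) / support(Ty)
    leverage(Tx -> Ty)   = support(Tx -> Ty) - support(Tx) * support(Ty)
    conviction(Tx -> Ty) = (1 - support(Ty)) / (1 - confidence(Tx -> Ty))

where P(S) is the number of transactions containing every member of S.
Conviction at confidence = 1 is reported as +inf (serialised as "inf") and
passes any finite lower bound.  All screening thresholds are strict lower
bounds; the defaults are support > 20%, confidence > 35%, lift > 1,
leverage > 0, conviction > 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ParameterError, ValidationError
from .io import FunctionAssociation, TargetPrediction

logger = logging.getLogger("fctf.arm")

Itemset = frozenset


@dataclass(frozen=True)
class Transaction:
    """One index entity (component or disease) and its target set."""

    index_id: str
    origin: Literal["component", "function"]
    items: frozenset[str]


class TransactionSet:
    """An ordered transaction database with exact occurrence counting."""

    def __init__(self, transactions: Sequence[Transaction]):
        self.transactions = list(transactions)
        self._count_cache: dict[frozenset[str], int] = {}

    @property
    def N(self) -> int:
        return len(self.transactions)

    @property
    def items(self) -> set[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t.items
        return out

    def count(self, itemset: Iterable[str]) -> int:
        """P(itemset): number of transactions containing every item."""
        key = frozenset(itemset)
        cached = self._count_cache.get(key)
        if cached is None:
            cached = sum(1 for t in self.transactions if key <= t.items)
            self._count_cache[key] = cached
        return cached

    def support(self, itemset: Iterable[str]) -> float:
        if self.N == 0:
            raise ValidationError("empty transaction set has no support")
        return self.count(itemset) / self.N


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float
    leverage: float
    conviction: float  # math.inf when confidence == 1

    @property
    def label(self) -> str:
        left = ",".join(sorted(self.antecedent))
        right = ",".join(sorted(self.consequent))
        return f"{left} -> {right}"

    def metrics(self) -> dict[str, float]:
        return {
            "support": self.support,
            "confidence": self.confidence,
            "lift": self.lift,
            "leverage": self.leverage,
            "conviction": self.conviction,
        }


def _as_fraction(value: float, name: str) -> float:
    """Thresholds given as percents (values > 1) normalise to fractions."""
    if value is None:
        return value
    if name in ("min_support", "min_confidence") and value > 1.0:
        return value / 100.0
    return value


@dataclass
class RuleThresholds:
    """Strict lower bounds on the five rule measures.

    Support and confidence accept percent notation (values > 1 are divided
    by 100 on construction).
    """

    min_support: float = 0.20
    min_confidence: float = 0.35
    min_lift: float = 1.0
    min_leverage: float = 0.0
    min_conviction: float = 0.0

    def __post_init__(self) -> None:
        self.min_support = _as_fraction(self.min_support, "min_support")
        self.min_confidence = _as_fraction(self.min_confidence, "min_confidence")

    def accepts(self, rule: AssociationRule) -> bool:
        return (
            rule.support > self.min_support
            and rule.confidence > self.min_confidence
            and rule.lift > self.min_lift
            and rule.leverage > self.min_leverage
            and rule.conviction > self.min_conviction
        )


# ---------------------------------------------------------------------------
# Transaction construction
# ---------------------------------------------------------------------------

def build_transactions(
    predictions: Sequence[TargetPrediction],
    functions: Sequence[FunctionAssociation] = (),
    mode: Literal["components", "functions", "both"] = "both",
) -> TransactionSet:
    """One transaction per component and/or per disease (its target set).

    Index entities with empty target sets are dropped; ``mode="both"`` with
    an empty function catalog falls back to components with a warning.
    """
    if mode not in ("components", "functions", "both"):
        raise ParameterError(f"unknown transaction mode {mode!r}")
    if mode == "both" and not functions:
        logger.warning("no function associations; falling back to components-only transactions")
        mode = "components"

    transactions: list[Transaction] = []
    if mode in ("components", "both"):
        by_component: dict[str, set[str]] = {}
        for p in predictions:
            by_component.setdefault(p.component, set()).add(p.target)
        for component in by_component:
            items = by_component[component]
            if items:
                transactions.append(Transaction(component, "component", frozenset(items)))
    if mode in ("functions", "both"):
        by_disease: dict[str, set[str]] = {}
        for a in functions:
            by_disease.setdefault(a.disease, set()).add(a.target)
        for disease in by_disease:
            items = by_disease[disease]
            if items:
                transactions.append(Transaction(disease, "function", frozenset(items)))
    if not transactions:
        raise ValidationError("no index entity has a non-empty target set")
    logger.info("transactions: N=%d (mode=%s)", len(transactions), mode)
    return TransactionSet(transactions)


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------

def mine_frequent_itemsets(
    tx: TransactionSet,
    min_support: float,
    max_size: int = 2,
) -> list[tuple[frozenset[str], float]]:
    """Level-wise Apriori: itemsets of size <= max_size with support > min_support.

    Candidates of size k are joins of frequent (k-1)-sets sharing a
    (k-2)-prefix, pruned by downward closure before counting.  The strict
    support comparison excludes itemsets exactly at the threshold.
    """
    min_support = _as_fraction(min_support, "min_support")
    if not 0 < min_support <= 1:
        raise ParameterError(f"min_support must be in (0, 1], got {min_support}")
    if max_size < 1:
        raise ParameterError(f"max_size must be >= 1, got {max_size}")

    frequent: list[tuple[frozenset[str], float]] = []
    level: list[frozenset[str]] = []
    for item in sorted(tx.items):
        s = tx.support([item])
        if s > min_support:
            level.append(frozenset([item]))
            frequent.append((frozenset([item]), s))

    k = 2
    while level and k <= max_size:
        frequent_prev = set(level)
        candidates: set[frozenset[str]] = set()
        ordered = [tuple(sorted(s)) for s in level]
        ordered.sort()
        for a, b in combinations(ordered, 2):
            if a[:-1] == b[:-1]:  # join on shared (k-2)-prefix
                candidate = frozenset(a) | frozenset(b)
                if all(candidate - {i} in frequent_prev for i in candidate):
                    candidates.add(candidate)
        level = []
        for candidate in sorted(candidates, key=sorted):
            s = tx.support(candidate)
            if s > min_support:
                level.append(candidate)
                frequent.append((candidate, s))
        k += 1

    frequent.sort(key=lambda pair: (len(pair[0]), sorted(pair[0])))
    logger.info("frequent itemsets: %d (support > %g, size <= %d)", len(frequent), min_support, max_size)
    return frequent


# ---------------------------------------------------------------------------
# Rule derivation and filtering
# ---------------------------------------------------------------------------

def _make_rule(tx: TransactionSet, antecedent: frozenset, consequent: frozenset) -> AssociationRule:
    n = tx.N
    union_count = tx.count(antecedent | consequent)
    x_count = tx.count(antecedent)
    y_count = tx.count(consequent)
    support = union_count / n
    confidence = union_count / x_count
    support_y = y_count / n
    lift = confidence / support_y
    leverage = support - (x_count / n) * support_y
    if union_count == x_count:  # confidence == 1 exactly
        conviction = math.inf
    else:
        conviction = (1.0 - support_y) / (1.0 - confidence)
    return AssociationRule(antecedent, consequent, support, confidence, lift, leverage, conviction)


def derive_rules(
    itemsets: Sequence[tuple[frozenset[str], float]],
    tx: TransactionSet,
) -> list[AssociationRule]:
    """Every ordered non-empty disjoint partition of each frequent itemset."""
    all_items = tx.items
    rules: list[AssociationRule] = []
    for itemset, _support in itemsets:
        if not itemset <= all_items:
            raise ValidationError(f"itemset {sorted(itemset)} not drawn from this transaction set")
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        for r in range(1, len(members)):
            for antecedent in combinations(members, r):
                ante = frozenset(antecedent)
                rules.append(_make_rule(tx, ante, itemset - ante))
    return rules


def filter_rules(
    rules: Iterable[AssociationRule],
    thresholds: RuleThresholds | None = None,
) -> list[AssociationRule]:
    """Keep rules passing all five strict bounds; deterministic ordering.

    Sorted by support desc, confidence desc, then rule label.
    """
    thresholds = thresholds or RuleThresholds()
    kept = [r for r in rules if thresholds.accepts(r)]
    kept.sort(key=lambda r: (-r.support, -r.confidence, r.label))
    logger.info("rule filter: %d kept", len(kept))
    return kept


def item_role_frequencies(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Per target symbol: appearances as antecedent and as consequent."""
    ante: dict[str, int] = {}
    cons: dict[str, int] = {}
    for rule in rules:
        for item in rule.antecedent:
            ante[item] = ante.get(item, 0) + 1
        for item in rule.consequent:
            cons[item] = cons.get(item, 0) + 1
    symbols = sorted(set(ante) | set(cons))
    frame = pd.DataFrame(
        {
            "target": symbols,
            "antecedent_count": [ante.get(s, 0) for s in symbols],
            "consequent_count": [cons.get(s, 0) for s in symbols],
        }
    )
    frame["total"] = frame["antecedent_count"] + frame["consequent_count"]
    frame = frame.sort_values(
        ["total", "target"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Tabular rule view; conviction +inf serialises as the string 'inf'."""
    return pd.DataFrame(
        [
            {
                "antecedent": ",".join(sorted(r.antecedent)),
                "consequent": ",".join(sorted(r.consequent)),
                **r.metrics(),
            }
            for r in rules
        ],
        columns=["antecedent", "consequent", "support", "confidence", "lift", "leverage", "conviction"],
    )


def write_rules(rules: Sequence[AssociationRule], path) -> None:
    frame = rules_to_frame(rules)
    for column in ("support", "confidence", "lift", "leverage", "conviction"):
        frame[column] = frame[column].map(
            lambda v: "inf" if math.isinf(v) else f"{v:.6f}"
        )
    frame.to_csv(path, sep="\t", index=False)
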