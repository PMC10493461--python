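"""Entropy-weight method (EWM) and TOPSIS ranking of filtered rules.

The five rule measures form a decision matrix (rules x criteria, all
benefit-type).  EWM assigns each criterion an objective weight from its
information entropy — criteria whose values are more dispersed across rules
carry more information and receive larger weights:

    p_ij = x_ij / sum_i x_ij
    e_j  = -(1 / ln n) * sum_i p_ij ln p_ij      (0 ln 0 := 0)
    w_j  = (1 - e_j) / sum_k (1 - e_k)

TOPSIS then scores each rule by its closeness to the ideal:
vector-normalise each column, multiply by the weights, take the
per-criterion best (positive ideal) and worst (negative ideal), and set
C = d- / (d+ + d-) where d+/- are Euclidean distances to the two ideals.

Infinite conviction values are capped at the finite column maximum before
analysis, and any column containing negatives is min-shifted to be
non-negative for the entropy step; both transforms are deterministic and
logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .arm import AssociationRule
from .errors import DegenerateMatrixError, ParameterError

logger = logging.getLogger("fctf.mcda")

CRITERIA = ("support", "confidence", "lift", "leverage", "conviction")


@dataclass
class DecisionMatrix:
    alternatives: list[str]
    criteria: list[str]
    values: np.ndarray  # alternatives x criteria, finite
    orientations: list[str]  # "benefit" or "cost" per criterion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.alternatives), len(self.criteria)):
            raise ParameterError("decision-matrix shape does not match labels")
        if len(self.alternatives) < 2 or len(self.criteria) < 1:
            raise ParameterError("need at least 2 alternatives and 1 criterion")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("decision matrix must be finite; cap infinities first")

    @classmethod
    def from_rules(cls, rules: Sequence[AssociationRule]) -> "DecisionMatrix":
        """Rules x five-metric matrix with the +inf conviction transform."""
        if len(rules) < 2:
            raise ParameterError("ranking needs at least 2 rules")
        grid = np.array([[r.metrics()[c] for c in CRITERIA] for r in rules], dtype=float)
        for j in range(grid.shape[1]):
            column = grid[:, j]
            infinite = np.isinf(column)
            if infinite.any():
                finite = column[~infinite]
                cap = float(finite.max()) if finite.size else 1.0
                column[infinite] = cap
                logger.info("capped %d infinite %s values at %g", infinite.sum(), CRITERIA[j], cap)
        return cls(
            alternatives=[r.label for r in rules],
            criteria=list(CRITERIA),
            values=grid,
            orientations=["benefit"] * len(CRITERIA),
        )


@dataclass
class CriterionWeights:
    criteria: list[str]
    entropy: np.ndarray
    weight: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            c: {"entropy": float(e), "weight": float(w)}
            for c, e, w in zip(self.criteria, self.entropy, self.weight)
        }


@dataclass
class TopsisResult:
    alternatives: list[str]
    d_plus: np.ndarray
    d_minus: np.ndarray
    score: np.ndarray
    ranking: list[str]  # score desc, lexicographic ties

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "alternative": self.alternatives,
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "score": self.score,
            }
        )
        order = {a: i for i, a in enumerate(self.ranking)}
        frame["rank"] = [order[a] + 1 for a in self.alternatives]
        return frame.sort_values("rank", kind="mergesort").reset_index(drop=True)


def entropy_weights(matrix: DecisionMatrix) -> CriterionWeights:
    """Objective criterion weights from column-wise information entropy.

    Constant columns carry no information: entropy 1, weight 0.  If every
    column is constant the weights are undefined and a degenerate error is
    raised (callers may fall back to equal weights explicitly).
    """
    x = matrix.values.copy()
    n = x.shape[0]
    if n < 2:
        raise ParameterError("entropy weighting needs at least 2 alternatives")
    for j in range(x.shape[1]):
        low = x[:, j].min()
        if low < 0:  # min-shift so proportions are defined
            x[:, j] = x[:, j] - low
            logger.info("min-shifted criterion %s by %g", matrix.criteria[j], -low)

    entropies = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        total = x[:, j].sum()
        if total == 0:
            entropies[j] = 1.0
            continue
        p = x[:, j] / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        entropies[j] = -terms.sum() / math.log(n)
    entropies = np.clip(entropies, 0.0, 1.0)

    dispersion = 1.0 - entropies
    if dispersion.sum() <= 0:
        raise DegenerateMatrixError(
            "all criterion columns are constant; supply equal weights explicitly"
        )
    weights = dispersion / dispersion.sum()
    return CriterionWeights(list(matrix.criteria), entropies, weights)


def topsis(matrix: DecisionMatrix, weights: CriterionWeights) -> TopsisResult:
    """Closeness-to-ideal scores under vector normalisation."""
    if list(weights.criteria) != list(matrix.criteria):
        raise ParameterError("weights do not match the decision-matrix criteria")
    w = np.asarray(weights.weight, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ParameterError(f"weights must sum to 1, got {w.sum()}")

    x = matrix.values
    norms = np.sqrt((x ** 2).sum(axis=0))
    keep = norms > 0
    if not keep.all():
        dropped = [c for c, k in zip(matrix.criteria, keep) if not k]
        logger.warning("dropping zero-norm criteria (no information): %s", dropped)
    x = x[:, keep]
    norms = norms[keep]
    w = w[keep]
    orientations = [o for o, k in zip(matrix.orientations, keep) if k]

    v = (x / norms) * w
    ideal_pos = np.array(
        [v[:, j].max() if orientations[j] == "benefit" else v[:, j].min() for j in range(v.shape[1])]
    )
    ideal_neg = np.array(
        [v[:, j].min() if orientations[j] == "benefit" else v[:, j].max() for j in range(v.shape[1])]
    )
    d_plus = np.sqrt(((v - ideal_pos) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - ideal_neg) ** 2).sum(axis=1))
    total = d_plus + d_minus
    # An alternative equal to both ideals (fully degenerate row space)
    # coincides with the positive ideal, so closeness is 1.
    score = np.where(total > 0, d_minus / np.where(total > 0, total, 1.0), 1.0)

    ranking = [
        a for a, _ in sorted(
            zip(matrix.alternatives, score), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    return TopsisResult(list(matrix.alternatives), d_plus, d_minus, score, ranking)


@dataclass
class RuleRanking:
    """Composite rank_rules output: ranked table + the weights behind it."""

    table: pd.DataFrame
    weights: CriterionWeights
    topsis: TopsisResult


def equal_weights(criteria: Sequence[str]) -> CriterionWeights:
    """The documented fallback when every criterion column is constant."""
    k = len(criteria)
    return CriterionWeights(list(criteria), np.ones(k), np.full(k, 1.0 / k))


def rank_rules(rules: Sequence[AssociationRule]) -> RuleRanking:
    """Compose matrix build -> entropy weights -> TOPSIS on filtered rules.

    A fully constant decision matrix (every rule identical on all five
    measures) carries no ranking information; entropy weights are undefined
    there and the documented equal-weights fallback is applied.
    """
    if len(rules) < 2:
        raise ParameterError("ranking needs at least 2 rules")
    matrix = DecisionMatrix.from_rules(rules)
    try:
        weights = entropy_weights(matrix)
    except DegenerateMatrixError:
        logger.warning("constant decision matrix; falling back to equal weights")
        weights = equal_weights(matrix.criteria)
    result = topsis(matrix, weights)

    by_label = {r.label: r for r in rules}
    rows = []
    for rank, label in enumerate(result.ranking, start=1):
        i = result.alternatives.index(label)
        rule = by_label[label]
        rows.append(
            {
                "rank": rank,
                "antecedent": ",".join(sorted(rule.antecedent)),
                "consequent": ",".join(sorted(rule.consequent)),
                **rule.metrics(),
                "d_plus": float(result.d_plus[i]),
                "d_minus": float(result.d_minus[i]),
                "score": float(result.score[i]),
            }
        )
    table = pd.DataFrame(rows)
    return RuleRanking(table=table, weights=weights, topsis=result)
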