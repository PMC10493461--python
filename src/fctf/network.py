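"""Tripartite component-target-function network and degree statistics.

Degree centrality is the sole node weight used downstream: for a component
it counts predicted targets, for a target it counts either associated
components (CT layer) or associated diseases (TF layer), and for a disease
category it counts target-disease edges.  Nodes with degree > 1 are flagged
as "supported", since a co-occurrence rule built on a degree-1 node has no
repeated evidence behind it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import ParameterError, ValidationError
from .io import FunctionAssociation, InteractionEdge, TargetPrediction, normalize_disease

logger = logging.getLogger("fctf.network")

DEGREE_LAYERS = ("component", "target_ct", "target_tf", "function", "category")

#: A node's association is considered supported only above this degree.
SUPPORT_DEGREE = 1


@dataclass
class TripartiteNetwork:
    component_nodes: set[str]
    target_nodes: set[str]
    function_nodes: set[str]
    ct_edges: set[tuple[str, str]]
    tf_edges: set[tuple[str, str]]
    disease_category: dict[str, str] = field(default_factory=dict)
    #: targets with only function edges (no component evidence), kept but flagged
    function_only_targets: set[str] = field(default_factory=set)


@dataclass
class DegreeTable:
    """Per-node degrees for one layer, descending with lexicographic ties."""

    layer: str
    entries: list[tuple[str, int]]

    def top(self, n: int = 10) -> list[tuple[str, int]]:
        return self.entries[:n]

    def supported(self) -> list[str]:
        return [node for node, deg in self.entries if deg > SUPPORT_DEGREE]


@dataclass
class VennResult:
    """Exact region counts for a small family of sets.

    ``region_counts`` maps a frozenset of set names to the number of
    elements lying in exactly those sets; regions are disjoint and sum to
    the size of the union.
    """

    set_names: list[str]
    region_counts: dict[frozenset[str], int]
    member_lists: dict[frozenset[str], list[str]]

    def count(self, *names: str) -> int:
        return self.region_counts.get(frozenset(names), 0)

    def members(self, *names: str) -> list[str]:
        return self.member_lists.get(frozenset(names), [])

    def to_json_dict(self) -> dict:
        key = lambda region: " & ".join(sorted(region))
        return {
            "set_names": self.set_names,
            "region_counts": {key(r): c for r, c in sorted(
                self.region_counts.items(), key=lambda kv: key(kv[0]))},
            "member_lists": {key(r): m for r, m in sorted(
                self.member_lists.items(), key=lambda kv: key(kv[0]))},
        }


def _sorted_degrees(counts: dict[str, int]) -> list[tuple[str, int]]:
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def build_network(
    components: Sequence,
    predictions: Sequence[TargetPrediction],
    functions: Sequence[FunctionAssociation],
) -> TripartiteNetwork:
    """Assemble the component-target-function tripartite edge structure."""
    if not predictions:
        raise ValidationError("cannot build a network without component-target edges")
    ct_edges = {(p.component, p.target) for p in predictions}
    tf_edges = {(a.target, a.disease) for a in functions}
    component_nodes = {c for c, _ in ct_edges}
    ct_targets = {t for _, t in ct_edges}
    tf_targets = {t for t, _ in tf_edges}
    network = TripartiteNetwork(
        component_nodes=component_nodes,
        target_nodes=ct_targets | tf_targets,
        function_nodes={d for _, d in tf_edges},
        ct_edges=ct_edges,
        tf_edges=tf_edges,
        disease_category={a.disease: a.category for a in functions},
        function_only_targets=tf_targets - ct_targets,
    )
    logger.info(
        "network: %d components, %d targets, %d diseases, %d CT + %d TF edges",
        len(network.component_nodes), len(network.target_nodes),
        len(network.function_nodes), len(ct_edges), len(tf_edges),
    )
    return network


def degree(network: TripartiteNetwork, layer: str) -> DegreeTable:
    """Degree centrality of one node class.

    layer:
      - ``component``  targets per component
      - ``target_ct``  components per target
      - ``target_tf``  diseases per target
      - ``function``   targets per disease
      - ``category``   target-disease edges per disease category
    """
    if layer not in DEGREE_LAYERS:
        raise ParameterError(f"unknown degree layer {layer!r}; choose from {DEGREE_LAYERS}")
    counts: dict[str, int] = {}
    if layer == "component":
        for c, _ in network.ct_edges:
            counts[c] = counts.get(c, 0) + 1
    elif layer == "target_ct":
        for _, t in network.ct_edges:
            counts[t] = counts.get(t, 0) + 1
    elif layer == "target_tf":
        for t, _ in network.tf_edges:
            counts[t] = counts.get(t, 0) + 1
    elif layer == "function":
        for _, d in network.tf_edges:
            counts[d] = counts.get(d, 0) + 1
    else:  # category
        for _, d in network.tf_edges:
            cat = network.disease_category.get(d, "unknown")
            counts[cat] = counts.get(cat, 0) + 1
    return DegreeTable(layer=layer, entries=_sorted_degrees(counts))


def unique_targets(predictions: Sequence[TargetPrediction]) -> list[str]:
    """Deduplicated target symbols in first-appearance order."""
    seen: dict[str, None] = {}
    for p in predictions:
        seen.setdefault(p.target, None)
    logger.info("unique targets: %d of %d predictions", len(seen), len(predictions))
    return list(seen)


def category_overlap(
    functions: Sequence[FunctionAssociation],
    categories: Sequence[str],
) -> VennResult:
    """Venn regions over the deduplicated disease names of each category."""
    if not 2 <= len(categories) <= 6:
        raise ParameterError("category_overlap expects between 2 and 6 categories")
    vocabulary = {a.category for a in functions}
    unknown = [c for c in categories if c not in vocabulary]
    if unknown:
        raise ParameterError(f"unknown categories: {unknown}; known: {sorted(vocabulary)}")
    sets = {
        c: {normalize_disease(a.disease) for a in functions if a.category == c}
        for c in categories
    }
    return venn(sets)


def venn(named_sets: dict[str, set[str]]) -> VennResult:
    """Exact disjoint-region decomposition of a family of named sets."""
    names = list(named_sets)
    universe = set().union(*named_sets.values()) if named_sets else set()
    region_members: dict[frozenset[str], list[str]] = {}
    for element in universe:
        region = frozenset(n for n in names if element in named_sets[n])
        region_members.setdefault(region, []).append(element)
    return VennResult(
        set_names=names,
        region_counts={r: len(m) for r, m in region_members.items()},
        member_lists={r: sorted(m) for r, m in region_members.items()},
    )


def interaction_summary(
    edges: Iterable[InteractionEdge],
) -> tuple[int, int, DegreeTable]:
    """Node count, edge count and degree table of the simple PPI graph.

    Isolated nodes cannot occur: nodes exist only as edge endpoints.
    """
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.protein_a, e.protein_b, weight=e.combined_score)
    table = DegreeTable(
        layer="interaction",
        entries=_sorted_degrees({n: d for n, d in graph.degree()}),
    )
    return graph.number_of_nodes(), graph.number_of_edges(), table
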