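"""Integration and scoring: assemble records into results and rank them.

The per-edge record sets retrieved during execution are joined into result
sub-graphs, each matching the topology of the query graph: an assignment of
one concrete entity to every query node such that every query edge is
supported by at least one record consistent with the assignment. Results
are then scored on a composite of three bounded components —

* support: how many distinct records back the result (more independent
  evidence scores higher, with diminishing returns),
* path length: how far the result's open nodes sit from the pinned nodes
  (shorter explanatory chains score higher),
* semantic similarity: mean Normalized Google Distance (NGD) derived
  similarity over entity pairs adjacent in the result, computed from a
  local term/pair co-occurrence table.

NGD between terms x and y with occurrence counts f(x), f(y), joint count
f(x,y) and corpus size N is

    NGD(x, y) = (max(log f(x), log f(y)) - log f(x, y))
                / (log N - min(log f(x), log f(y)))

which is 0 for a term with itself and grows as the terms co-occur less;
terms that never co-occur are infinitely distant and contribute zero
similarity. The composite weighting is implementation-defined and fully
exposed through :class:`ScoreConfig`.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import json

from .errors import FedKGError, UndefinedTermError
from .executor import Record, RecordSet
from .query import Curie, QueryGraph

__all__ = [
    "ResultGraph",
    "CooccurrenceTable",
    "ScoreConfig",
    "ScoreBreakdown",
    "assemble",
    "ngd",
    "ngd_similarity",
    "score_result",
    "rank_results",
]

logger = logging.getLogger(__name__)


@dataclass
class ResultGraph:
    """One answer: entities bound to every query node, records per edge."""

    node_bindings: dict[str, Curie]
    edge_bindings: dict[str, list[Record]]
    score: "ScoreBreakdown | None" = None

    def binding_key(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted((qnode_id, str(c)) for qnode_id, c in self.node_bindings.items()))


class CooccurrenceTable:
    """Term and pair occurrence counts over a notional corpus.

    Invariants enforced at load: all counts non-negative, f(x) <= N and
    f(x, y) <= min(f(x), f(y)) for every stored pair. The joint count of a
    term with itself defaults to f(x) when not explicitly stored, so
    NGD(x, x) = 0 for any known term.
    """

    def __init__(self, N: int, terms: dict[str, int], pairs: dict[frozenset, int]) -> None:
        if N <= 0:
            raise FedKGError("co-occurrence corpus size N must be positive")
        for term, count in terms.items():
            if count < 0 or count > N:
                raise FedKGError(f"occurrence count of {term!r} outside [0, N]")
        for pair, count in pairs.items():
            members = sorted(pair)
            lowest = min(terms.get(t, 0) for t in members)
            if count < 0 or count > lowest:
                raise FedKGError(f"pair count for {members} exceeds min of term counts")
        self.N = N
        self.terms = dict(terms)
        self.pairs = dict(pairs)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "CooccurrenceTable":
        pairs = {frozenset((a, b)): int(c) for a, b, c in raw.get("pairs", [])}
        return cls(N=int(raw["N"]), terms={k: int(v) for k, v in raw.get("terms", {}).items()}, pairs=pairs)

    @classmethod
    def load(cls, path: str | Path) -> "CooccurrenceTable":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def f(self, term: str) -> int:
        return self.terms.get(term, 0)

    def f2(self, x: str, y: str) -> int:
        if x == y:
            return self.pairs.get(frozenset((x,)), self.f(x))
        return self.pairs.get(frozenset((x, y)), 0)


def ngd(x: str, y: str, table: CooccurrenceTable) -> float:
    """Normalized Google Distance between two terms; symmetric, >= 0."""
    fx, fy = table.f(x), table.f(y)
    if fx <= 0 or fy <= 0:
        raise UndefinedTermError(f"term with zero occurrences: {x if fx <= 0 else y!r}")
    f2 = table.f2(x, y)
    if f2 <= 0:
        return math.inf
    log_fx, log_fy = math.log(fx), math.log(fy)
    numerator = max(log_fx, log_fy) - math.log(f2)
    denominator = math.log(table.N) - min(log_fx, log_fy)
    if numerator <= 0:
        return 0.0
    if denominator <= 0:
        return math.inf
    return numerator / denominator


def ngd_similarity(x: str, y: str, table: CooccurrenceTable, cap: float) -> float:
    """Similarity in [0, 1]: 1 - NGD/cap, clamped at 0 (cap saturates)."""
    distance = ngd(x, y, table)
    if math.isinf(distance):
        return 0.0
    return max(0.0, 1.0 - distance / cap)


@dataclass(frozen=True)
class ScoreConfig:
    """Weights of the composite score and the NGD saturation point.

    Weights are normalized to sum to one on construction; ``ngd_cap`` is
    the distance at which similarity saturates to zero.
    """

    w_paths: float = 1.0 / 3.0
    w_length: float = 1.0 / 3.0
    w_sim: float = 1.0 / 3.0
    ngd_cap: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_paths, self.w_length, self.w_sim) < 0:
            raise FedKGError("score weights must be non-negative")
        total = self.w_paths + self.w_length + self.w_sim
        if total <= 0:
            raise FedKGError("score weights must not all be zero")
        if self.ngd_cap <= 0:
            raise FedKGError("ngd_cap must be positive")
        if abs(total - 1.0) > 1e-9:
            object.__setattr__(self, "w_paths", self.w_paths / total)
            object.__setattr__(self, "w_length", self.w_length / total)
            object.__setattr__(self, "w_sim", self.w_sim / total)


@dataclass(frozen=True)
class ScoreBreakdown:
    n_paths: int
    mean_path_length: float
    sim: float
    total: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n_paths": self.n_paths,
            "mean_path_length": self.mean_path_length,
            "sim": self.sim,
            "total": self.total,
        }


def _pair_support(query_graph: QueryGraph, record_set: RecordSet):
    support: dict[str, dict[tuple[Curie, Curie], list[Record]]] = {}
    for qedge_id, qedge in query_graph.qedges.items():
        pairs: dict[tuple[Curie, Curie], list[Record]] = {}
        for record in record_set.records(qedge_id):
            pairs.setdefault(record.qedge_endpoints(qedge), []).append(record)
        support[qedge_id] = pairs
    return support


def _join_order(query_graph: QueryGraph) -> list[str]:
    """Order qedges so each (after the first) touches an already-seen qnode."""
    remaining = dict(query_graph.qedges)
    order: list[str] = []
    seen_qnodes: set[str] = set()
    while remaining:
        next_id = None
        for qedge_id in sorted(remaining):
            edge = remaining[qedge_id]
            if not order or edge.subject_qnode in seen_qnodes or edge.object_qnode in seen_qnodes:
                next_id = qedge_id
                break
        if next_id is None:  # disconnected component (rejected at parse time)
            next_id = sorted(remaining)[0]
        edge = remaining.pop(next_id)
        order.append(next_id)
        seen_qnodes.update((edge.subject_qnode, edge.object_qnode))
    return order


def assemble(
    query_graph: QueryGraph,
    record_set: RecordSet,
    pinned: dict[str, set[Curie]] | None = None,
) -> list[ResultGraph]:
    """Enumerate all entity assignments supported by >= 1 record per edge.

    ``pinned`` optionally overrides the allowed entities at pinned query
    nodes (the engine passes canonicalized pins, since records always carry
    canonical identifiers while the query may pin an alias). Results are
    deduplicated on node bindings with edge bindings merged; the returned
    list is deterministically ordered by binding key.
    """
    if pinned is None:
        pinned = {
            n.qnode_id: set(n.ids) for n in query_graph.qnodes.values() if n.pinned
        }

    def allowed(qnode_id: str, entity: Curie) -> bool:
        return qnode_id not in pinned or entity in pinned[qnode_id]

    if not query_graph.qedges:
        results = [
            ResultGraph(node_bindings={qnode_id: entity}, edge_bindings={})
            for qnode_id, entities in sorted(pinned.items())
            for entity in sorted(entities)
        ]
        return results

    support = _pair_support(query_graph, record_set)
    assignments: list[dict[str, Curie]] = [{}]
    for qedge_id in _join_order(query_graph):
        qedge = query_graph.qedges[qedge_id]
        extended: list[dict[str, Curie]] = []
        for assignment in assignments:
            for subject_entity, object_entity in support[qedge_id]:
                if not allowed(qedge.subject_qnode, subject_entity):
                    continue
                if not allowed(qedge.object_qnode, object_entity):
                    continue
                bound_subject = assignment.get(qedge.subject_qnode)
                bound_object = assignment.get(qedge.object_qnode)
                if bound_subject is not None and bound_subject != subject_entity:
                    continue
                if bound_object is not None and bound_object != object_entity:
                    continue
                new = dict(assignment)
                new[qedge.subject_qnode] = subject_entity
                new[qedge.object_qnode] = object_entity
                extended.append(new)
        assignments = extended
        if not assignments:
            return []

    results: dict[tuple, ResultGraph] = {}
    for assignment in assignments:
        edge_bindings = {
            qedge_id: list(
                support[qedge_id][
                    (
                        assignment[query_graph.qedges[qedge_id].subject_qnode],
                        assignment[query_graph.qedges[qedge_id].object_qnode],
                    )
                ]
            )
            for qedge_id in query_graph.qedges
        }
        result = ResultGraph(node_bindings=dict(assignment), edge_bindings=edge_bindings)
        results.setdefault(result.binding_key(), result)
    return [results[key] for key in sorted(results)]


def _open_node_distances(query_graph: QueryGraph) -> list[int]:
    """Shortest qedge distance of each open (unpinned) qnode from a pin."""
    adjacency: dict[str, set[str]] = {n: set() for n in query_graph.qnodes}
    for edge in query_graph.qedges.values():
        adjacency[edge.subject_qnode].add(edge.object_qnode)
        adjacency[edge.object_qnode].add(edge.subject_qnode)
    distances: dict[str, int] = {
        n.qnode_id: 0 for n in query_graph.qnodes.values() if n.pinned
    }
    queue = deque(distances)
    while queue:
        node = queue.popleft()
        for neighbor in adjacency[node]:
            if neighbor not in distances:
                distances[neighbor] = distances[node] + 1
                queue.append(neighbor)
    return [d for qnode_id, d in distances.items() if not query_graph.qnodes[qnode_id].pinned]


def support_factor(n_paths: int) -> float:
    """Diminishing-returns transform of record count: 1 - 1/(1 + ln(1+n))."""
    return 1.0 - 1.0 / (1.0 + math.log(1.0 + n_paths))


def length_factor(mean_path_length: float) -> float:
    """1/L for mean path length L >= 1: shorter chains score higher."""
    return 1.0 / max(mean_path_length, 1.0)


def score_result(
    result: ResultGraph,
    query_graph: QueryGraph,
    table: CooccurrenceTable,
    config: ScoreConfig = ScoreConfig(),
) -> ScoreBreakdown:
    """Composite score in [0, 1]; monotone in support, anti-monotone in NGD.

    The similarity component averages over the entity pairs adjacent in the
    result (one pair per query edge); pairs with terms absent from the
    co-occurrence table are skipped and logged, and when no pair is
    computable the component is zero.
    """
    n_paths = sum(len(records) for records in result.edge_bindings.values())
    distances = _open_node_distances(query_graph)
    mean_path_length = (sum(distances) / len(distances)) if distances else 1.0

    sims: list[float] = []
    for qedge_id, qedge in query_graph.qedges.items():
        x = str(result.node_bindings[qedge.subject_qnode])
        y = str(result.node_bindings[qedge.object_qnode])
        try:
            sims.append(ngd_similarity(x, y, table, config.ngd_cap))
        except UndefinedTermError:
            logger.debug("qedge %r: term missing from co-occurrence table", qedge_id)
    sim = (sum(sims) / len(sims)) if sims else 0.0

    total = (
        config.w_paths * support_factor(n_paths)
        + config.w_length * length_factor(mean_path_length)
        + config.w_sim * sim
    )
    return ScoreBreakdown(
        n_paths=n_paths, mean_path_length=mean_path_length, sim=sim, total=total
    )


def rank_results(results: list[ResultGraph]) -> list[ResultGraph]:
    """Descending total score; ties broken lexicographically on bindings."""
    for result in results:
        if result.score is None:
            raise FedKGError("rank_results requires scored results")
    return sorted(results, key=lambda r: (-r.score.total, r.binding_key()))
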