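"""Query-path planning: decompose a query graph into executable API calls.

For every query edge the planner consults the meta-KG for compatible
operations — in the forward direction (operation input on the edge's subject
side) and in reverse (input on the object side) — expanding category and
predicate constraints through the hierarchy. It also fixes an execution
order that chains hops: an edge is only executed once at least one of its
endpoints is bound, either pinned in the query or produced by an earlier
edge.

Matching semantics: an operation category matches a query-node category when
it is the same token or a descendant of it (never an ancestor, which would
fan out to overly broad APIs); a node or edge without constraints matches
everything; edge predicates are expanded through the predicate tree. The
candidate set is provably equivalent to a brute-force scan of every
operation in the registry with the same compatibility test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import FedKGError, PlanningError
from .hierarchy import CategoryHierarchy
from .query import QEdge, QNode, QueryGraph
from .registry import MetaKG, OperationAnnotation

__all__ = ["Candidate", "EdgePlan", "QueryPlan", "match_operations", "order_edges", "plan_query"]

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class Candidate:
    operation: OperationAnnotation
    direction: str  # FORWARD or REVERSE


@dataclass(frozen=True)
class EdgePlan:
    qedge_id: str
    candidates: tuple[Candidate, ...]


@dataclass
class QueryPlan:
    edge_order: list[str]
    edges: dict[str, EdgePlan]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "edge_order": list(self.edge_order),
            "edges": {
                qedge_id: [
                    {"op_id": c.operation.op_id, "direction": c.direction}
                    for c in plan.candidates
                ]
                for qedge_id, plan in self.edges.items()
            },
            "warnings": list(self.warnings),
        }


def _category_matches(op_category: str, qnode: QNode, hierarchy: CategoryHierarchy) -> bool:
    if not qnode.categories:
        return True
    return any(
        op_category in hierarchy.descendants(wanted)
        for wanted in qnode.categories
        if wanted in hierarchy.categories
    )


def _predicate_matches(op_predicate: str, qedge: QEdge, hierarchy: CategoryHierarchy) -> bool:
    if not qedge.predicates:
        return True
    return any(
        op_predicate in hierarchy.predicate_descendants(wanted)
        for wanted in qedge.predicates
        if wanted in hierarchy.predicates
    )


def match_operations(
    qedge: QEdge,
    qnodes: dict[str, QNode],
    meta_kg: MetaKG,
    hierarchy: CategoryHierarchy,
) -> EdgePlan:
    """All operations compatible with one query edge, in both directions.

    Candidates are ordered forward-before-reverse, then by ascending op_id,
    so plans are deterministic. An empty candidate list is legal here; it is
    surfaced as a warning (or an unplannable-query error) by `plan_query`.
    """
    subject = qnodes[qedge.subject_qnode]
    obj = qnodes[qedge.object_qnode]
    forward: list[Candidate] = []
    reverse: list[Candidate] = []
    for op_id in sorted(meta_kg.operations):
        op = meta_kg.operations[op_id]
        if not _predicate_matches(op.predicate, qedge, hierarchy):
            continue
        if _category_matches(op.input_category, subject, hierarchy) and _category_matches(
            op.output_category, obj, hierarchy
        ):
            forward.append(Candidate(operation=op, direction=FORWARD))
        if _category_matches(op.input_category, obj, hierarchy) and _category_matches(
            op.output_category, subject, hierarchy
        ):
            reverse.append(Candidate(operation=op, direction=REVERSE))
    return EdgePlan(qedge_id=qedge.qedge_id, candidates=tuple(forward + reverse))


def order_edges(query_graph: QueryGraph) -> list[str]:
    """Breadth-first edge order from the pinned nodes.

    Edges become eligible as soon as one endpoint is bound; ties within a
    breadth-first level are broken by ascending qedge_id. Deterministic for
    a given query graph.
    """
    bound = {n.qnode_id for n in query_graph.pinned_qnodes()}
    remaining = dict(query_graph.qedges)
    order: list[str] = []
    while remaining:
        level = sorted(
            qedge_id
            for qedge_id, edge in remaining.items()
            if edge.subject_qnode in bound or edge.object_qnode in bound
        )
        if not level:
            # impossible for a validated (connected, anchored) query graph
            raise FedKGError(f"unreachable qedges {sorted(remaining)}")
        for qedge_id in level:
            edge = remaining.pop(qedge_id)
            order.append(qedge_id)
            bound.update((edge.subject_qnode, edge.object_qnode))
    return order


def plan_query(
    query_graph: QueryGraph,
    meta_kg: MetaKG,
    hierarchy: CategoryHierarchy,
) -> QueryPlan:
    """Combine edge ordering with per-edge candidate operations.

    Raises :class:`PlanningError` when *no* edge has any candidate; edges
    that individually lack candidates produce structured warnings instead,
    since partial data may still be informative to the caller.
    """
    edges = {
        qedge_id: match_operations(qedge, query_graph.qnodes, meta_kg, hierarchy)
        for qedge_id, qedge in query_graph.qedges.items()
    }
    warnings = [
        f"qedge {qedge_id!r}: no compatible operation in the registry"
        for qedge_id in sorted(edges)
        if not edges[qedge_id].candidates
    ]
    if edges and all(not plan.candidates for plan in edges.values()):
        raise PlanningError("unplannable query: no registry operation serves any edge")
    for message in warnings:
        logger.warning(message)
    return QueryPlan(edge_order=order_edges(query_graph), edges=edges, warnings=warnings)
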