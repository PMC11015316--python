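"""TRAPI-style query graphs and response envelopes.

A query is a small graph: nodes are either *pinned* to concrete identifiers
(CURIEs) or left open with a semantic category constraint, and edges may be
constrained to predicates. The engine answers such a graph with a response
envelope echoing the query, a knowledge graph of the retrieved entities and
associations, and a list of scored results binding concrete entities to the
query nodes.

Only the ``ids``, ``categories`` and ``predicates`` constraint keys of the
Reasoner-API vocabulary are honored; serialization uses sorted keys so that
identical envelopes render byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

from .errors import CurieError, QueryValidationError

__all__ = [
    "Curie",
    "QNode",
    "QEdge",
    "QueryGraph",
    "ResponseEnvelope",
    "parse_curie",
    "parse_query_graph",
    "query_graph_to_dict",
    "serialize_response",
    "parse_response",
]


@dataclass(frozen=True, order=True)
class Curie:
    """Compact identifier ``prefix:local_id`` (e.g. ``NCBIGene:7157``)."""

    prefix: str
    local_id: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"


def parse_curie(text: str) -> Curie:
    """Split on the first colon; both parts must be non-empty."""
    if not isinstance(text, str) or ":" not in text:
        raise CurieError(f"not a CURIE (missing colon): {text!r}")
    prefix, _, local_id = text.partition(":")
    if not prefix or not local_id:
        raise CurieError(f"not a CURIE (empty part): {text!r}")
    return Curie(prefix=prefix, local_id=local_id)


@dataclass(frozen=True)
class QNode:
    qnode_id: str
    ids: tuple[Curie, ...] = ()
    categories: tuple[str, ...] = ()

    @property
    def pinned(self) -> bool:
        return bool(self.ids)


@dataclass(frozen=True)
class QEdge:
    qedge_id: str
    subject_qnode: str
    object_qnode: str
    predicates: tuple[str, ...] = ()


@dataclass(frozen=True)
class QueryGraph:
    qnodes: dict[str, QNode]
    qedges: dict[str, QEdge]

    def pinned_qnodes(self) -> list[QNode]:
        return [n for n in self.qnodes.values() if n.pinned]

    def edges_touching(self, qnode_id: str) -> list[QEdge]:
        return [
            e
            for e in self.qedges.values()
            if qnode_id in (e.subject_qnode, e.object_qnode)
        ]


def _validate(graph: QueryGraph) -> QueryGraph:
    if not graph.qnodes:
        raise QueryValidationError("query graph has no nodes")
    for edge in graph.qedges.values():
        for endpoint in (edge.subject_qnode, edge.object_qnode):
            if endpoint not in graph.qnodes:
                raise QueryValidationError(
                    f"qedge {edge.qedge_id!r} references missing qnode {endpoint!r}"
                )
        if edge.subject_qnode == edge.object_qnode:
            raise QueryValidationError(f"qedge {edge.qedge_id!r} is a self-loop")
    if not any(n.pinned for n in graph.qnodes.values()):
        raise QueryValidationError("unanchored query: no qnode is pinned to identifiers")
    # weak connectivity over the undirected qnode adjacency
    seen = set()
    stack = [next(iter(graph.qnodes))]
    adjacency: dict[str, set[str]] = {n: set() for n in graph.qnodes}
    for edge in graph.qedges.values():
        adjacency[edge.subject_qnode].add(edge.object_qnode)
        adjacency[edge.object_qnode].add(edge.subject_qnode)
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adjacency[node])
    if seen != set(graph.qnodes):
        missing = sorted(set(graph.qnodes) - seen)
        raise QueryValidationError(f"disconnected query: unreachable qnodes {missing}")
    return graph


def parse_query_graph(document: dict[str, Any] | str) -> QueryGraph:
    """Parse ``{"message": {"query_graph": {...}}}`` into a validated graph.

    Validation is total: the result is either a fully validated QueryGraph
    or a :class:`QueryValidationError`, never a partially built object.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise QueryValidationError(f"query document is not valid JSON: {exc}") from exc
    if not isinstance(document, dict):
        raise QueryValidationError("query document must be a JSON object")
    try:
        qg = document["message"]["query_graph"]
        raw_nodes = qg["nodes"]
        raw_edges = qg.get("edges", {})
    except (KeyError, TypeError) as exc:
        raise QueryValidationError("document lacks message.query_graph.nodes") from exc

    qnodes: dict[str, QNode] = {}
    for qnode_id, spec in raw_nodes.items():
        spec = spec or {}
        try:
            ids = tuple(parse_curie(c) for c in spec.get("ids") or ())
        except CurieError as exc:
            raise QueryValidationError(f"qnode {qnode_id!r}: {exc}") from exc
        categories = tuple(spec.get("categories") or ())
        qnodes[qnode_id] = QNode(qnode_id=qnode_id, ids=ids, categories=categories)

    qedges: dict[str, QEdge] = {}
    for qedge_id, spec in raw_edges.items():
        spec = spec or {}
        for key in ("subject", "object"):
            if key not in spec:
                raise QueryValidationError(f"qedge {qedge_id!r} missing {key!r}")
        qedges[qedge_id] = QEdge(
            qedge_id=qedge_id,
            subject_qnode=spec["subject"],
            object_qnode=spec["object"],
            predicates=tuple(spec.get("predicates") or ()),
        )
    return _validate(QueryGraph(qnodes=qnodes, qedges=qedges))


def query_graph_to_dict(graph: QueryGraph) -> dict[str, Any]:
    nodes: dict[str, Any] = {}
    for qnode_id, node in graph.qnodes.items():
        spec: dict[str, Any] = {}
        if node.ids:
            spec["ids"] = [str(c) for c in node.ids]
        if node.categories:
            spec["categories"] = list(node.categories)
        nodes[qnode_id] = spec
    edges: dict[str, Any] = {}
    for qedge_id, edge in graph.qedges.items():
        spec = {"subject": edge.subject_qnode, "object": edge.object_qnode}
        if edge.predicates:
            spec["predicates"] = list(edge.predicates)
        edges[qedge_id] = spec
    return {"nodes": nodes, "edges": edges}


@dataclass
class ResponseEnvelope:
    """Echoed query graph + retrieved knowledge graph + scored results.

    ``kg_nodes`` maps CURIE strings to ``{"category", "label"}``;
    ``kg_edges`` maps edge ids to ``{"subject", "predicate", "object",
    "api_name", "op_id", "qedge_id", "retrieval_direction"}``; each result
    carries ``node_bindings`` (qnode id -> list of CURIE strings),
    ``edge_bindings`` (qedge id -> list of kg edge ids), a scalar ``score``
    and its ``score_components``.
    """

    query_graph: QueryGraph
    kg_nodes: dict[str, dict[str, Any]] = field(default_factory=dict)
    kg_edges: dict[str, dict[str, Any]] = field(default_factory=dict)
    results: list[dict[str, Any]] = field(default_factory=list)

    def validate(self) -> None:
        for i, result in enumerate(self.results):
            for qnode_id, curies in result["node_bindings"].items():
                if qnode_id not in self.query_graph.qnodes:
                    raise QueryValidationError(f"result {i}: unknown qnode {qnode_id!r}")
                for curie in curies:
                    if curie not in self.kg_nodes:
                        raise QueryValidationError(
                            f"result {i}: binding to missing knowledge-graph node {curie!r}"
                        )
            for qedge_id, edge_ids in result["edge_bindings"].items():
                if qedge_id not in self.query_graph.qedges:
                    raise QueryValidationError(f"result {i}: unknown qedge {qedge_id!r}")
                for edge_id in edge_ids:
                    if edge_id not in self.kg_edges:
                        raise QueryValidationError(
                            f"result {i}: binding to missing knowledge-graph edge {edge_id!r}"
                        )


def _envelope_to_dict(envelope: ResponseEnvelope) -> dict[str, Any]:
    return {
        "message": {
            "query_graph": query_graph_to_dict(envelope.query_graph),
            "knowledge_graph": {
                "nodes": envelope.kg_nodes,
                "edges": envelope.kg_edges,
            },
            "results": [
                {
                    "node_bindings": {
                        k: [{"id": c} for c in v]
                        for k, v in result["node_bindings"].items()
                    },
                    "edge_bindings": {
                        k: [{"id": e} for e in v]
                        for k, v in result["edge_bindings"].items()
                    },
                    "score": result.get("score"),
                    "score_components": result.get("score_components"),
                }
                for result in envelope.results
            ],
        }
    }


def serialize_response(envelope: ResponseEnvelope) -> str:
    """Deterministic JSON rendering (sorted keys); validates bindings first."""
    envelope.validate()
    return json.dumps(_envelope_to_dict(envelope), indent=2, sort_keys=True)


def parse_response(text: str) -> ResponseEnvelope:
    """Inverse of :func:`serialize_response` (round-trip identity)."""
    doc = json.loads(text)
    message = doc["message"]
    graph = parse_query_graph({"message": {"query_graph": message["query_graph"]}})
    kg = message.get("knowledge_graph", {"nodes": {}, "edges": {}})
    results = [
        {
            "node_bindings": {
                k: [b["id"] for b in v] for k, v in r["node_bindings"].items()
            },
            "edge_bindings": {
                k: [b["id"] for b in v] for k, v in r["edge_bindings"].items()
            },
            "score": r.get("score"),
            "score_components": r.get("score_components"),
        }
        for r in message.get("results", [])
    ]
    envelope = ResponseEnvelope(
        query_graph=graph,
        kg_nodes=kg.get("nodes", {}),
        kg_edges=kg.get("edges", {}),
        results=results,
    )
    envelope.validate()
    return envelope
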