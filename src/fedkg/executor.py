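"""Query-path execution: batched sub-queries, ID extraction, normalization.

Given a query plan, the executor renders each candidate operation's request
template for the entities bound at the edge's input side, sends the requests
through a pluggable :class:`Transport`, extracts output identifiers from the
responses via the operation's declared id path, translates identifiers to
canonical form through a local normalizer table, and emits provenance-tagged
:class:`Record` associations grouped per query edge.

Identifier translation is what makes chaining work across APIs that name
the same entity differently (an NCBI gene id versus an Ensembl gene id):
both record endpoints are canonicalized, and when an input entity does not
carry the prefix an operation expects, the executor first looks for an
equivalent identifier under the required prefix before giving up on it.

Operations fail independently: a transport failure for one operation is
logged and skipped, and the remaining candidates still contribute records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Protocol

import json

from .errors import TransportError
from .idpath import extract_ids
from .planner import FORWARD, QueryPlan
from .query import Curie, QEdge, QueryGraph, parse_curie
from .registry import OperationAnnotation

__all__ = [
    "Request",
    "Transport",
    "NormalizedEntity",
    "NormalizerTable",
    "Record",
    "RecordSet",
    "render_subquery",
    "extract_ids",
    "normalize",
    "execute_edge",
    "execute_plan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Request:
    """One rendered API call; ``inputs`` keeps the batched local ids."""

    op_id: str
    server_url: str
    path: str
    method: str
    payload: str
    inputs: tuple[str, ...]


class Transport(Protocol):
    """Contract for sending a rendered request to an API.

    Returns the parsed response document, or raises
    :class:`~fedkg.errors.TransportError` on failure. Fixture transports are
    pure: the same request always yields the same response.
    """

    def call(self, request: Request) -> Any:  # pragma: no cover - protocol
        ...


@dataclass(frozen=True)
class NormalizedEntity:
    curie: Curie
    label: str
    category: str | None
    normalized: bool  # False when the identifier was unknown to the table


class NormalizerTable:
    """Local identifier-equivalence table (node-normalizer stand-in).

    Built from clusters ``{canonical, category, label, equivalents}``; every
    member of a cluster resolves to the cluster's canonical identifier.
    Canonicalization is idempotent by construction, and unknown identifiers
    pass through unchanged (flagged) rather than being dropped — federated
    sources disagree, and a pass-through record is more useful than a hole.
    """

    def __init__(self, clusters: Iterable[dict[str, Any]] = ()) -> None:
        self._clusters: dict[str, dict[str, Any]] = {}
        self._index: dict[str, str] = {}
        for cluster in clusters:
            canonical = str(cluster["canonical"])
            entry = {
                "canonical": canonical,
                "category": cluster.get("category"),
                "label": cluster.get("label", canonical),
                "equivalents": [str(e) for e in cluster.get("equivalents", [])],
            }
            self._clusters[canonical] = entry
            self._index[canonical] = canonical
            for equivalent in entry["equivalents"]:
                self._index[equivalent] = canonical

    @classmethod
    def load(cls, path: str | Path) -> "NormalizerTable":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))

    def normalize(self, curie: Curie) -> NormalizedEntity:
        canonical = self._index.get(str(curie))
        if canonical is None:
            return NormalizedEntity(curie=curie, label=str(curie), category=None, normalized=False)
        entry = self._clusters[canonical]
        return NormalizedEntity(
            curie=parse_curie(canonical),
            label=entry["label"],
            category=entry["category"],
            normalized=True,
        )

    def alias_with_prefix(self, curie: Curie, prefix: str) -> Curie | None:
        """An identifier equivalent to ``curie`` under ``prefix``, if any."""
        if curie.prefix == prefix:
            return curie
        canonical = self._index.get(str(curie))
        if canonical is None:
            return None
        entry = self._clusters[canonical]
        for text in (canonical, *entry["equivalents"]):
            candidate = parse_curie(text)
            if candidate.prefix == prefix:
                return candidate
        return None


def normalize(curie: Curie, table: NormalizerTable) -> NormalizedEntity:
    """Canonicalize one identifier through the equivalence table."""
    return table.normalize(curie)


@dataclass(frozen=True)
class Record:
    """One retrieved association, bound to a query edge with provenance."""

    subject: Curie
    subject_category: str
    subject_label: str
    predicate: str
    object: Curie
    object_category: str
    object_label: str
    qedge_id: str
    api_name: str
    op_id: str
    retrieval_direction: str = FORWARD

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (str(self.subject), self.predicate, str(self.object), self.qedge_id, self.op_id)

    def qedge_endpoints(self, qedge: QEdge) -> tuple[Curie, Curie]:
        """Entities bound at (qedge.subject, qedge.object).

        A reverse-direction record was retrieved from the edge's object side,
        so its retrieval subject binds to the query edge's object.
        """
        if self.retrieval_direction == FORWARD:
            return self.subject, self.object
        return self.object, self.subject


@dataclass
class RecordSet:
    """Records grouped by query edge, deduplicated on
    (subject, predicate, object, qedge_id, op_id)."""

    by_qedge: dict[str, list[Record]] = field(default_factory=dict)
    _keys: set[tuple[str, str, str, str, str]] = field(default_factory=set, repr=False)

    def add(self, record: Record) -> bool:
        if record.key in self._keys:
            return False
        self._keys.add(record.key)
        self.by_qedge.setdefault(record.qedge_id, []).append(record)
        return True

    def records(self, qedge_id: str) -> list[Record]:
        return self.by_qedge.get(qedge_id, [])

    def all_records(self) -> list[Record]:
        return [r for records in self.by_qedge.values() for r in records]

    def __len__(self) -> int:
        return len(self._keys)


def render_subquery(operation: OperationAnnotation, input_curies: Iterable[Curie]) -> list[Request]:
    """Render batched requests for the inputs carrying the right prefix.

    Inputs whose prefix differs from the operation's declared input prefix
    are dropped here (callers translate identifiers beforehand); the rest are
    chunked into ceil(n / max_batch) requests with ``{inputs}`` replaced by
    the comma-joined local ids. Zero eligible inputs is an empty request
    list, not an error.
    """
    eligible = [c for c in input_curies if c.prefix == operation.input_prefix]
    requests = []
    for start in range(0, len(eligible), operation.max_batch):
        chunk = eligible[start : start + operation.max_batch]
        local_ids = tuple(c.local_id for c in chunk)
        requests.append(
            Request(
                op_id=operation.op_id,
                server_url=operation.server_url,
                path=operation.path,
                method=operation.method,
                payload=operation.request_template.replace("{inputs}", ",".join(local_ids)),
                inputs=local_ids,
            )
        )
    return requests


def _entity_meta(entity: NormalizedEntity, fallback_category: str) -> tuple[str, str]:
    category = entity.category if entity.category is not None else fallback_category
    return category, entity.label


def execute_edge(
    edge_plan,
    qedge: QEdge,
    bound: dict[str, set[Curie]],
    transport: Transport,
    normalizer: NormalizerTable,
) -> tuple[list[Record], list[str]]:
    """Run every candidate operation of one query edge; returns (records, warnings).

    Each input entity is sent as its own request so that every output
    identifier is attributed to the exact input that produced it — the
    minimal response dialect does not echo inputs, and sound multi-hop joins
    need that attribution. Entities lacking the operation's input prefix are
    first translated through the normalizer's equivalents; entities with no
    equivalent under the required prefix are skipped for that operation.
    """
    records: list[Record] = []
    warnings: list[str] = []
    seen: set[tuple[str, str, str, str, str]] = set()
    for candidate in edge_plan.candidates:
        op = candidate.operation
        input_qnode = qedge.subject_qnode if candidate.direction == FORWARD else qedge.object_qnode
        inputs = sorted(bound.get(input_qnode, set()))
        failed = False
        for canonical_input in inputs:
            alias = normalizer.alias_with_prefix(canonical_input, op.input_prefix)
            if alias is None:
                logger.debug(
                    "op %s: no %s equivalent for %s", op.op_id, op.input_prefix, canonical_input
                )
                continue
            for request in render_subquery(op, [alias]):
                try:
                    document = transport.call(request)
                except TransportError as exc:
                    message = f"operation {op.op_id!r} failed: {exc}"
                    warnings.append(message)
                    logger.warning(message)
                    failed = True
                    break
                subject_entity = normalizer.normalize(canonical_input)
                subject_category, subject_label = _entity_meta(subject_entity, op.input_category)
                for output_id in extract_ids(document, op.response_id_path):
                    output_entity = normalizer.normalize(Curie(op.output_prefix, output_id))
                    object_category, object_label = _entity_meta(output_entity, op.output_category)
                    record = Record(
                        subject=subject_entity.curie,
                        subject_category=subject_category,
                        subject_label=subject_label,
                        predicate=op.predicate,
                        object=output_entity.curie,
                        object_category=object_category,
                        object_label=object_label,
                        qedge_id=qedge.qedge_id,
                        api_name=op.api_name,
                        op_id=op.op_id,
                        retrieval_direction=candidate.direction,
                    )
                    if record.key not in seen:
                        seen.add(record.key)
                        records.append(record)
            if failed:
                break
    if edge_plan.candidates and not records and len(warnings) == len(edge_plan.candidates):
        logger.warning("qedge %r: every candidate operation failed", qedge.qedge_id)
    return records, warnings


def execute_plan(
    plan: QueryPlan,
    query_graph: QueryGraph,
    transport: Transport,
    normalizer: NormalizerTable,
) -> tuple[RecordSet, list[str]]:
    """Execute edges in plan order, chaining outputs into later inputs.

    The input set for each edge is the union of the query's pinned
    identifiers (canonicalized) and the entities produced at the shared
    query node by earlier edges; a node that never receives entities
    propagates empty inputs, so downstream edges simply yield no records.
    """
    bound: dict[str, set[Curie]] = {}
    for qnode in query_graph.qnodes.values():
        if qnode.pinned:
            bound[qnode.qnode_id] = {normalizer.normalize(c).curie for c in qnode.ids}
    record_set = RecordSet()
    all_warnings: list[str] = []
    for qedge_id in plan.edge_order:
        qedge = query_graph.qedges[qedge_id]
        records, warnings = execute_edge(plan.edges[qedge_id], qedge, bound, transport, normalizer)
        all_warnings.extend(warnings)
        for record in records:
            record_set.add(record)
            subject_entity, object_entity = record.qedge_endpoints(qedge)
            for qnode_id, entity in (
                (qedge.subject_qnode, subject_entity),
                (qedge.object_qnode, object_entity),
            ):
                if not query_graph.qnodes[qnode_id].pinned:
                    bound.setdefault(qnode_id, set()).add(entity)
    return record_set, all_warnings
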