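"""High-level pipeline: one call from query graph to scored response.

Execution proceeds in the three phases the engine is organized around:
query-path planning against the meta-KG, query-path execution over a
transport with identifier normalization, and integration — assembling
per-edge records into result sub-graphs matching the query topology,
scoring and ranking them — into a response envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .executor import NormalizerTable, RecordSet, Transport, execute_plan
from .hierarchy import CategoryHierarchy
from .planner import QueryPlan, plan_query
from .query import Curie, QueryGraph, ResponseEnvelope
from .registry import APISpec, MetaKG, RegistryConfig, load_registry
from .scoring import (
    CooccurrenceTable,
    ResultGraph,
    ScoreConfig,
    assemble,
    rank_results,
    score_result,
)

__all__ = ["Engine", "answer_query"]


def _edge_id(record) -> str:
    return "|".join(record.key)


def _build_envelope(
    query_graph: QueryGraph,
    record_set: RecordSet,
    results: list[ResultGraph],
    normalizer: NormalizerTable,
) -> ResponseEnvelope:
    envelope = ResponseEnvelope(query_graph=query_graph)
    for record in record_set.all_records():
        for curie, category, label in (
            (record.subject, record.subject_category, record.subject_label),
            (record.object, record.object_category, record.object_label),
        ):
            envelope.kg_nodes.setdefault(str(curie), {"category": category, "label": label})
        envelope.kg_edges[_edge_id(record)] = {
            "subject": str(record.subject),
            "predicate": record.predicate,
            "object": str(record.object),
            "qedge_id": record.qedge_id,
            "api_name": record.api_name,
            "op_id": record.op_id,
            "retrieval_direction": record.retrieval_direction,
        }
    for result in results:
        for curie in result.node_bindings.values():
            if str(curie) not in envelope.kg_nodes:
                entity = normalizer.normalize(curie)
                envelope.kg_nodes[str(curie)] = {
                    "category": entity.category,
                    "label": entity.label,
                }
        envelope.results.append(
            {
                "node_bindings": {
                    qnode_id: [str(curie)]
                    for qnode_id, curie in result.node_bindings.items()
                },
                "edge_bindings": {
                    qedge_id: [_edge_id(r) for r in records]
                    for qedge_id, records in result.edge_bindings.items()
                },
                "score": result.score.total if result.score else None,
                "score_components": result.score.to_dict() if result.score else None,
            }
        )
    return envelope


def answer_query(
    query_graph: QueryGraph,
    meta_kg: MetaKG,
    hierarchy: CategoryHierarchy,
    transport: Transport,
    normalizer: NormalizerTable,
    cooccurrence: CooccurrenceTable,
    score_config: ScoreConfig = ScoreConfig(),
) -> tuple[ResponseEnvelope, QueryPlan, list[str]]:
    """Run all three phases; returns (envelope, plan, warnings).

    Raises :class:`~fedkg.errors.PlanningError` when no registry operation
    serves any query edge; a plannable query unsupported by the data simply
    yields an envelope with empty results.
    """
    plan = plan_query(query_graph, meta_kg, hierarchy)
    record_set, warnings = execute_plan(plan, query_graph, transport, normalizer)
    pinned: dict[str, set[Curie]] = {
        n.qnode_id: {normalizer.normalize(c).curie for c in n.ids}
        for n in query_graph.qnodes.values()
        if n.pinned
    }
    results = assemble(query_graph, record_set, pinned=pinned)
    for result in results:
        result.score = score_result(result, query_graph, cooccurrence, score_config)
    ranked = rank_results(results)
    return _build_envelope(query_graph, record_set, ranked, normalizer), plan, warnings


@dataclass
class Engine:
    """Loaded registry, vocabulary and tables, ready to answer queries."""

    hierarchy: CategoryHierarchy
    specs: list[APISpec]
    meta_kg: MetaKG
    normalizer: NormalizerTable
    cooccurrence: CooccurrenceTable
    score_config: ScoreConfig = field(default_factory=ScoreConfig)

    @classmethod
    def from_config(cls, config_path: str | Path, score_config: ScoreConfig | None = None) -> "Engine":
        config = RegistryConfig.load(config_path)
        hierarchy, specs, meta_kg = load_registry(config)
        return cls(
            hierarchy=hierarchy,
            specs=specs,
            meta_kg=meta_kg,
            normalizer=NormalizerTable.load(config.normalizer_path),
            cooccurrence=CooccurrenceTable.load(config.cooccurrence_path),
            score_config=score_config or ScoreConfig(),
        )

    def answer(
        self, query_graph: QueryGraph, transport: Transport
    ) -> tuple[ResponseEnvelope, QueryPlan, list[str]]:
        return answer_query(
            query_graph,
            self.meta_kg,
            self.hierarchy,
            transport,
            self.normalizer,
            self.cooccurrence,
            self.score_config,
        )
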