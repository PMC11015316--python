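import random

import pytest
from hypothesis import given, settings, strategies as st

from fedkg.executor import (
    NormalizerTable,
    RecordSet,
    execute_edge,
    execute_plan,
    normalize,
    render_subquery,
)
from fedkg.idpath import extract_ids, parse_id_path
from fedkg.errors import IdPathError
from fedkg.planner import plan_query
from fedkg.query import Curie, parse_curie
from fedkg.synthetic import FixtureTransport

from conftest import NORMALIZER_CLUSTERS, RESPONSE_PATHS, ASSOCIATIONS


# --- sub-query rendering ---------------------------------------------------


def test_single_input_renders_direct_substitution(meta_kg):
    op = meta_kg.op("ctd_disease_gene")
    requests = render_subquery(op, [Curie("MONDO", "0005148")])
    assert len(requests) == 1
    assert requests[0].payload == "disease_ids=0005148"
    assert requests[0].inputs == ("0005148",)
    assert requests[0].method == "GET"


def test_five_inputs_with_max_batch_two_chunk_into_2_2_1(meta_kg):
    import dataclasses

    op = dataclasses.replace(meta_kg.op("ctd_disease_gene"), max_batch=2)
    curies = [Curie("MONDO", str(i)) for i in range(5)]
    requests = render_subquery(op, curies)
    assert [len(r.inputs) for r in requests] == [2, 2, 1]
    assert requests[0].payload == "disease_ids=0,1"
    assert requests[2].payload == "disease_ids=4"


def test_inputs_with_wrong_prefix_render_no_requests(meta_kg):
    op = meta_kg.op("ctd_disease_gene")
    assert render_subquery(op, [Curie("DOID", "9352"), Curie("NCBIGene", "1")]) == []


# --- response id extraction ------------------------------------------------


def test_flat_hits_path_extracts_in_order():
    doc = {"hits": [{"id": "7157"}, {"id": "1017"}]}
    assert extract_ids(doc, "hits[].id") == ["7157", "1017"]


def test_missing_key_yields_no_results_not_an_error():
    assert extract_ids({"other": 1}, "hits[].id") == []
    assert extract_ids({"hits": [{"name": "x"}]}, "hits[].id") == []
    assert extract_ids({"hits": "not-a-list"}, "hits[].id") == []


def test_duplicates_preserved():
    doc = {"hits": [{"id": "1"}, {"id": "1"}]}
    assert extract_ids(doc, "hits[].id") == ["1", "1"]


@pytest.mark.parametrize("bad", ["", "a..b", "a[", "a]b", "hits[]id", ".a", "a."])
def test_path_syntax_errors_raise_at_parse_time(bad):
    with pytest.raises(IdPathError):
        parse_id_path(bad)


def _recursive_descent(node, keys):
    """Independent oracle: plain recursion over (key, map_array) pairs."""
    if not keys:
        return [str(node)] if isinstance(node, (str, int, float)) and not isinstance(node, bool) else []
    (key, is_array), rest = keys[0], keys[1:]
    if not isinstance(node, dict) or key not in node:
        return []
    value = node[key]
    if is_array:
        if not isinstance(value, list):
            return []
        out = []
        for item in value:
            out.extend(_recursive_descent(item, rest))
        return out
    return _recursive_descent(value, rest)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=40, deadline=None)
def test_nested_extraction_equals_recursive_descent_oracle(seed):
    rng = random.Random(seed)
    path = "a.b[].c[].id"
    doc = {
        "a": {
            "b": [
                {
                    "c": [
                        {"id": str(rng.randrange(100))}
                        for _ in range(rng.randrange(3))
                    ]
                    + ([{"noid": 1}] if rng.random() < 0.3 else [])
                }
                for _ in range(rng.randrange(4))
            ]
        }
    }
    keys = [("a", False), ("b", True), ("c", True), ("id", False)]
    assert extract_ids(doc, path) == _recursive_descent(doc, keys)


# --- identifier normalization ----------------------------------------------


def test_equivalent_identifier_maps_to_canonical(normalizer):
    entity = normalize(parse_curie("ENSEMBL:ENSG00000141510"), normalizer)
    assert str(entity.curie) == "NCBIGene:7157"
    assert entity.label == "TP53"
    assert entity.normalized


def test_canonical_input_is_a_fixed_point(normalizer):
    once = normalize(parse_curie("NCBIGene:7157"), normalizer)
    twice = normalize(once.curie, normalizer)
    assert once.curie == twice.curie


def test_unknown_curie_passes_through_flagged(normalizer):
    entity = normalize(parse_curie("UMLS:C000000"), normalizer)
    assert str(entity.curie) == "UMLS:C000000"
    assert not entity.normalized


def test_alias_lookup_by_prefix(normalizer):
    alias = normalizer.alias_with_prefix(parse_curie("NCBIGene:1017"), "ENSEMBL")
    assert str(alias) == "ENSEMBL:ENSG00000123374"
    assert normalizer.alias_with_prefix(parse_curie("CHEBI:15365"), "ENSEMBL") is None


# --- edge execution --------------------------------------------------------


def _bound(**kwargs):
    return {k: {parse_curie(c) for c in v} for k, v in kwargs.items()}


def test_fixture_disease_gene_edge_returns_two_records(
    fig2_query, meta_kg, hierarchy, transport, normalizer
):
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    records, warnings = execute_edge(
        plan.edges["e0"], fig2_query.qedges["e0"], _bound(n0=["MONDO:0005148"]),
        transport, normalizer,
    )
    assert warnings == []
    # ctd: 2 records; monarch duplicates one association with distinct provenance
    subjects_objects = {(str(r.subject), str(r.object), r.op_id) for r in records}
    assert subjects_objects == {
        ("MONDO:0005148", "NCBIGene:1017", "ctd_disease_gene"),
        ("MONDO:0005148", "NCBIGene:7157", "ctd_disease_gene"),
        ("MONDO:0005148", "NCBIGene:1017", "monarch_disease_gene"),
    }
    assert all(r.subject_label == "type 2 diabetes" for r in records)


def test_failing_operation_is_isolated_with_warning(
    fig2_query, meta_kg, hierarchy, normalizer
):
    broken = FixtureTransport(
        response_paths=RESPONSE_PATHS, tables=ASSOCIATIONS, failing={"ctd_disease_gene"}
    )
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    records, warnings = execute_edge(
        plan.edges["e0"], fig2_query.qedges["e0"], _bound(n0=["MONDO:0005148"]),
        broken, normalizer,
    )
    assert len(warnings) == 1 and "ctd_disease_gene" in warnings[0]
    assert {r.op_id for r in records} == {"monarch_disease_gene"}
    assert {str(r.object) for r in records} == {"NCBIGene:1017"}


def test_same_association_from_two_apis_kept_as_two_records(
    fig2_query, meta_kg, hierarchy, transport, normalizer
):
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    records, _ = execute_edge(
        plan.edges["e0"], fig2_query.qedges["e0"], _bound(n0=["MONDO:0005148"]),
        transport, normalizer,
    )
    duplicated = [
        r for r in records
        if (str(r.subject), str(r.object)) == ("MONDO:0005148", "NCBIGene:1017")
    ]
    assert len(duplicated) == 2
    assert {r.op_id for r in duplicated} == {"ctd_disease_gene", "monarch_disease_gene"}
    # dedupe key: re-adding identical records into a RecordSet is a no-op
    record_set = RecordSet()
    for r in records + records:
        record_set.add(r)
    assert len(record_set) == len(records)


def test_alias_pinned_input_is_translated_before_prefix_filtering(
    fig2_query, meta_kg, hierarchy, transport, normalizer
):
    # pin via the DOID alias; the executor resolves it to the MONDO form the
    # operation expects
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    canonical = normalizer.normalize(parse_curie("DOID:9352")).curie
    records, _ = execute_edge(
        plan.edges["e0"], fig2_query.qedges["e0"], {"n0": {canonical}},
        transport, normalizer,
    )
    assert {str(r.object) for r in records} == {"NCBIGene:1017", "NCBIGene:7157"}


def test_input_with_no_equivalent_under_required_prefix_is_skipped(
    fig2_query, meta_kg, hierarchy, transport, normalizer
):
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    records, warnings = execute_edge(
        plan.edges["e0"], fig2_query.qedges["e0"],
        {"n0": {parse_curie("UMLS:C000000")}}, transport, normalizer,
    )
    assert records == [] and warnings == []


# --- plan execution --------------------------------------------------------


def test_two_hop_chaining_feeds_first_hop_outputs_into_second(
    fig2_query, meta_kg, hierarchy, transport, normalizer
):
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    record_set, warnings = execute_plan(plan, fig2_query, transport, normalizer)
    assert warnings == []
    e0_objects = {str(r.object) for r in record_set.records("e0")}
    e1_subjects = {str(r.subject) for r in record_set.records("e1")}
    assert e1_subjects <= e0_objects
    assert e1_subjects == {"NCBIGene:1017"}
    assert {str(r.object) for r in record_set.records("e1")} == {"CHEBI:15365", "CHEBI:6801"}


def test_single_edge_plan_equals_execute_edge(meta_kg, hierarchy, transport, normalizer):
    from fedkg.query import parse_query_graph

    graph = parse_query_graph(
        {
            "message": {
                "query_graph": {
                    "nodes": {"n0": {"ids": ["MONDO:0005148"], "categories": ["Disease"]},
                              "n1": {"categories": ["Gene"]}},
                    "edges": {"e0": {"subject": "n0", "object": "n1"}},
                }
            }
        }
    )
    plan = plan_query(graph, meta_kg, hierarchy)
    record_set, _ = execute_plan(plan, graph, transport, normalizer)
    records, _ = execute_edge(
        plan.edges["e0"], graph.qedges["e0"], _bound(n0=["MONDO:0005148"]),
        transport, normalizer,
    )
    assert sorted(r.key for r in record_set.records("e0")) == sorted(r.key for r in records)


def test_empty_first_hop_propagates_empty_downstream(
    meta_kg, hierarchy, transport, normalizer
):
    from fedkg.query import parse_query_graph

    graph = parse_query_graph(
        {
            "message": {
                "query_graph": {
                    "nodes": {"n0": {"ids": ["MONDO:0099999"], "categories": ["Disease"]},
                              "n1": {"categories": ["Gene"]},
                              "n2": {"categories": ["ChemicalEntity"]}},
                    "edges": {"e0": {"subject": "n0", "object": "n1"},
                              "e1": {"subject": "n1", "object": "n2"}},
                }
            }
        }
    )
    plan = plan_query(graph, meta_kg, hierarchy)
    record_set, _ = execute_plan(plan, graph, transport, normalizer)
    assert len(record_set) == 0
    assert record_set.records("e0") == [] and record_set.records("e1") == []


def test_execution_is_deterministic_on_fixture_transport(
    fig2_query, meta_kg, hierarchy, normalizer
):
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    runs = []
    for _ in range(2):
        transport = FixtureTransport(response_paths=RESPONSE_PATHS, tables=ASSOCIATIONS)
        record_set, _ = execute_plan(plan, fig2_query, transport, normalizer)
        runs.append([r.key for r in record_set.all_records()])
    assert runs[0] == runs[1]


def test_records_cite_only_planned_operations_and_normalized_endpoints(
    fig2_query, meta_kg, hierarchy, transport, normalizer
):
    plan = plan_query(fig2_query, meta_kg, hierarchy)
    record_set, _ = execute_plan(plan, fig2_query, transport, normalizer)
    for qedge_id, records in record_set.by_qedge.items():
        planned = {c.operation.op_id for c in plan.edges[qedge_id].candidates}
        for record in records:
            assert record.op_id in planned
            # normalization idempotence: endpoints are already canonical
            assert normalizer.normalize(record.subject).curie == record.subject
            assert normalizer.normalize(record.object).curie == record.object
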