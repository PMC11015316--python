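import math
import random

import pytest

from fedkg.errors import UndefinedTermError
from fedkg.executor import Record, RecordSet
from fedkg.query import Curie, parse_query_graph
from fedkg.scoring import (
    CooccurrenceTable,
    ScoreConfig,
    assemble,
    ngd,
    ngd_similarity,
    rank_results,
    score_result,
)

from oracles import brute_force_assemble


def make_record(qedge_id, subject, obj, op_id="opX", predicate="related_to",
                direction="forward"):
    s, o = Curie(*subject.split(":", 1)), Curie(*obj.split(":", 1))
    return Record(
        subject=s, subject_category="NamedThing", subject_label=str(s),
        predicate=predicate,
        object=o, object_category="NamedThing", object_label=str(o),
        qedge_id=qedge_id, api_name="API", op_id=op_id, retrieval_direction=direction,
    )


def record_set(*records):
    rs = RecordSet()
    for r in records:
        rs.add(r)
    return rs


ONE_EDGE_QUERY = {
    "message": {
        "query_graph": {
            "nodes": {"n0": {"ids": ["MONDO:0005148"]}, "n1": {"categories": ["Gene"]}},
            "edges": {"e0": {"subject": "n0", "object": "n1"}},
        }
    }
}


# --- assembly ---------------------------------------------------------------


def test_one_edge_query_with_three_distinct_objects_gives_three_results():
    graph = parse_query_graph(ONE_EDGE_QUERY)
    rs = record_set(
        make_record("e0", "MONDO:0005148", "NCBIGene:1"),
        make_record("e0", "MONDO:0005148", "NCBIGene:2"),
        make_record("e0", "MONDO:0005148", "NCBIGene:3"),
    )
    results = assemble(graph, rs)
    assert len(results) == 3
    assert all(len(r.edge_bindings["e0"]) == 1 for r in results)
    assert {str(r.node_bindings["n1"]) for r in results} == {
        "NCBIGene:1", "NCBIGene:2", "NCBIGene:3"
    }


def test_two_hop_join_only_keeps_entities_supported_on_both_hops(fig2_query):
    # e0: D-G1, D-G2; e1: G1-C1, G1-C2  =>  (D,G1,C1) and (D,G1,C2); G2 joins nothing
    rs = record_set(
        make_record("e0", "MONDO:0005148", "NCBIGene:1017"),
        make_record("e0", "MONDO:0005148", "NCBIGene:7157"),
        make_record("e1", "NCBIGene:1017", "CHEBI:15365"),
        make_record("e1", "NCBIGene:1017", "CHEBI:6801"),
    )
    results = assemble(fig2_query, rs)
    bindings = {
        tuple(str(r.node_bindings[q]) for q in ("n0", "n1", "n2")) for r in results
    }
    assert bindings == {
        ("MONDO:0005148", "NCBIGene:1017", "CHEBI:15365"),
        ("MONDO:0005148", "NCBIGene:1017", "CHEBI:6801"),
    }


def test_multiple_supporting_records_merge_into_one_result():
    graph = parse_query_graph(ONE_EDGE_QUERY)
    rs = record_set(
        make_record("e0", "MONDO:0005148", "NCBIGene:1", op_id="opA"),
        make_record("e0", "MONDO:0005148", "NCBIGene:1", op_id="opB"),
    )
    results = assemble(graph, rs)
    assert len(results) == 1
    assert len(results[0].edge_bindings["e0"]) == 2


def test_record_at_pinned_node_with_other_entity_is_excluded():
    graph = parse_query_graph(ONE_EDGE_QUERY)
    rs = record_set(make_record("e0", "MONDO:0000001", "NCBIGene:1"))
    assert assemble(graph, rs) == []


def _random_instance(rng):
    n_qnodes = rng.randrange(2, 6)
    nodes = {"n0": {"ids": [f"X:{rng.randrange(3)}"]}}
    for i in range(1, n_qnodes):
        nodes[f"n{i}"] = {"categories": ["NamedThing"]}
    edges = {}
    # random spanning tree keeps the graph connected, plus chance extra edges
    for i in range(1, n_qnodes):
        j = rng.randrange(i)
        edges[f"e{i - 1}"] = {"subject": f"n{j}", "object": f"n{i}"}
    if n_qnodes > 2 and rng.random() < 0.4:
        a, b = rng.sample(range(n_qnodes), 2)
        edges[f"e{len(edges)}"] = {"subject": f"n{a}", "object": f"n{b}"}
    graph = parse_query_graph({"message": {"query_graph": {"nodes": nodes, "edges": edges}}})
    rs = RecordSet()
    n_records = rng.randrange(0, 60)
    for k in range(n_records):
        qedge_id = rng.choice(sorted(edges))
        rs.add(
            make_record(
                qedge_id,
                f"X:{rng.randrange(6)}",
                f"X:{rng.randrange(6)}",
                op_id=f"op{rng.randrange(3)}",
                direction=rng.choice(["forward", "reverse"]),
            )
        )
    return graph, rs


def test_assembly_equals_exhaustive_enumeration_on_random_instances():
    rng = random.Random(20240917)
    for _ in range(40):
        graph, rs = _random_instance(rng)
        got = {r.binding_key() for r in assemble(graph, rs)}
        assert got == brute_force_assemble(graph, rs)


def test_every_bound_record_is_consistent_with_its_result():
    rng = random.Random(5)
    for _ in range(20):
        graph, rs = _random_instance(rng)
        for result in assemble(graph, rs):
            for qedge_id, records in result.edge_bindings.items():
                qedge = graph.qedges[qedge_id]
                for record in records:
                    s, o = record.qedge_endpoints(qedge)
                    assert result.node_bindings[qedge.subject_qnode] == s
                    assert result.node_bindings[qedge.object_qnode] == o


# --- normalized google distance --------------------------------------------


def test_ngd_of_a_term_with_itself_is_zero():
    table = CooccurrenceTable(N=1000, terms={"x": 10}, pairs={})
    assert ngd("x", "x", table) == 0.0


def test_ngd_hand_derived_value():
    table = CooccurrenceTable(
        N=1000, terms={"x": 100, "y": 50}, pairs={frozenset(("x", "y")): 25}
    )
    assert ngd("x", "y", table) == pytest.approx(0.4627564263195186, abs=1e-12)
    assert ngd("x", "y", table) == pytest.approx(0.46276, abs=1e-4)


def test_ngd_symmetric_on_all_fixture_pairs(cooccurrence):
    terms = sorted(cooccurrence.terms)
    for x in terms:
        for y in terms:
            assert ngd(x, y, cooccurrence) == ngd(y, x, cooccurrence)


def test_terms_that_never_cooccur_are_infinitely_distant():
    table = CooccurrenceTable(N=1000, terms={"x": 10, "y": 10}, pairs={})
    assert math.isinf(ngd("x", "y", table))
    assert ngd_similarity("x", "y", table, cap=1.0) == 0.0


def test_zero_occurrence_term_is_undefined():
    table = CooccurrenceTable(N=1000, terms={"x": 10}, pairs={})
    with pytest.raises(UndefinedTermError):
        ngd("x", "z", table)


def test_ngd_monotone_non_increasing_in_joint_count():
    previous = math.inf
    for f2 in range(1, 26):
        table = CooccurrenceTable(
            N=1000, terms={"x": 100, "y": 50}, pairs={frozenset(("x", "y")): f2}
        )
        value = ngd("x", "y", table)
        assert value <= previous
        previous = value


def test_table_invariants_enforced():
    from fedkg.errors import FedKGError

    with pytest.raises(FedKGError):
        CooccurrenceTable(N=1000, terms={"x": 5, "y": 5}, pairs={frozenset(("x", "y")): 6})
    with pytest.raises(FedKGError):
        CooccurrenceTable(N=10, terms={"x": 50}, pairs={})


# --- composite scoring ------------------------------------------------------


def test_result_with_terms_absent_from_table_scores_on_support_and_length():
    graph = parse_query_graph(ONE_EDGE_QUERY)
    rs = record_set(make_record("e0", "MONDO:0005148", "NCBIGene:1"))
    table = CooccurrenceTable(N=1000, terms={}, pairs={})
    (result,) = assemble(graph, rs)
    breakdown = score_result(result, graph, table)
    assert breakdown.sim == 0.0
    # w_paths*g(1) + w_length*h(1) with equal thirds weighting
    assert breakdown.total == pytest.approx(0.469794630283453, abs=1e-12)


def test_extra_supporting_record_strictly_raises_the_score(cooccurrence):
    graph = parse_query_graph(ONE_EDGE_QUERY)
    one = record_set(make_record("e0", "MONDO:0005148", "NCBIGene:1017", op_id="opA"))
    two = record_set(
        make_record("e0", "MONDO:0005148", "NCBIGene:1017", op_id="opA"),
        make_record("e0", "MONDO:0005148", "NCBIGene:1017", op_id="opB"),
    )
    (r1,) = assemble(graph, one)
    (r2,) = assemble(graph, two)
    s1 = score_result(r1, graph, cooccurrence)
    s2 = score_result(r2, graph, cooccurrence)
    assert s2.total > s1.total


def test_two_hop_fixture_composite_matches_hand_evaluation(fig2_query, cooccurrence):
    rs = record_set(
        make_record("e0", "MONDO:0005148", "NCBIGene:1017", op_id="ctd"),
        make_record("e0", "MONDO:0005148", "NCBIGene:1017", op_id="monarch"),
        make_record("e1", "NCBIGene:1017", "CHEBI:15365", op_id="mychem"),
    )
    (result,) = assemble(fig2_query, rs)
    breakdown = score_result(result, fig2_query, cooccurrence)
    assert breakdown.n_paths == 3
    assert breakdown.mean_path_length == pytest.approx(1.5)
    assert breakdown.sim == pytest.approx(0.5504745239039022, abs=1e-12)
    assert breakdown.total == pytest.approx(0.5993604687913879, abs=1e-12)


def test_score_components_and_total_bounded_in_unit_interval(cooccurrence):
    rng = random.Random(11)
    graph = parse_query_graph(ONE_EDGE_QUERY)
    for _ in range(50):
        rs = RecordSet()
        for k in range(rng.randrange(1, 6)):
            rs.add(make_record("e0", "MONDO:0005148", "NCBIGene:1017", op_id=f"op{k}"))
        for result in assemble(graph, rs):
            b = score_result(result, graph, cooccurrence)
            assert 0.0 <= b.sim <= 1.0
            assert 0.0 <= b.total <= 1.0


def test_raising_pairwise_distance_never_raises_the_score(fig2_query):
    rs = record_set(
        make_record("e0", "MONDO:0005148", "NCBIGene:1017"),
        make_record("e1", "NCBIGene:1017", "CHEBI:15365"),
    )
    (result,) = assemble(fig2_query, rs)
    previous = math.inf
    for f2 in (25, 20, 10, 5, 1):
        table = CooccurrenceTable(
            N=1000,
            terms={"MONDO:0005148": 100, "NCBIGene:1017": 50, "CHEBI:15365": 25},
            pairs={
                frozenset(("MONDO:0005148", "NCBIGene:1017")): f2,
                frozenset(("NCBIGene:1017", "CHEBI:15365")): 10,
            },
        )
        total = score_result(result, fig2_query, table).total
        assert total <= previous
        previous = total


def test_custom_weights_are_normalized_and_respected():
    config = ScoreConfig(w_paths=2.0, w_length=1.0, w_sim=1.0)
    assert config.w_paths == pytest.approx(0.5)
    graph = parse_query_graph(ONE_EDGE_QUERY)
    rs = record_set(make_record("e0", "MONDO:0005148", "NCBIGene:1"))
    table = CooccurrenceTable(N=1000, terms={}, pairs={})
    (result,) = assemble(graph, rs)
    breakdown = score_result(result, graph, table, config)
    expected = 0.5 * (1 - 1 / (1 + math.log(2))) + 0.25 * 1.0
    assert breakdown.total == pytest.approx(expected)


# --- ranking ----------------------------------------------------------------


def _scored(graph, bindings_and_scores, cooccurrence):
    results = []
    for obj, score in bindings_and_scores:
        rs = record_set(make_record("e0", "MONDO:0005148", obj))
        (result,) = assemble(graph, rs)
        result.score = score_result(result, graph, cooccurrence)
        object.__setattr__(result.score, "total", score)
        results.append(result)
    return results


def test_rank_descending_by_total(cooccurrence):
    graph = parse_query_graph(ONE_EDGE_QUERY)
    results = _scored(
        graph,
        [("NCBIGene:1", 0.9), ("NCBIGene:2", 0.3), ("NCBIGene:3", 0.5)],
        cooccurrence,
    )
    ranked = rank_results(results)
    assert [r.score.total for r in ranked] == [0.9, 0.5, 0.3]


def test_ties_break_lexicographically_and_shuffles_do_not_matter(cooccurrence):
    graph = parse_query_graph(ONE_EDGE_QUERY)
    results = _scored(
        graph,
        [("NCBIGene:b", 0.5), ("NCBIGene:a", 0.5), ("NCBIGene:c", 0.5)],
        cooccurrence,
    )
    reference = [r.binding_key() for r in rank_results(results)]
    assert [k[1][1] for k in reference] == ["NCBIGene:a", "NCBIGene:b", "NCBIGene:c"]
    rng = random.Random(3)
    for _ in range(10):
        shuffled = list(results)
        rng.shuffle(shuffled)
        assert [r.binding_key() for r in rank_results(shuffled)] == reference
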