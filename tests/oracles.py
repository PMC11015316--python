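"""Independent brute-force oracles used to cross-check the engine.

These deliberately re-derive the semantics from first principles (straight
scans and exhaustive enumeration) without calling the planner, executor or
assembler code paths they check.
"""

import itertools
import json
import random

from fedkg.registry import parse_api_spec

from conftest import make_spec_doc


def ancestors_closure(tree, token):
    """Set of token plus all its ancestors, by walking parent links."""
    out = set()
    node = token
    while node is not None:
        out.add(node)
        node = tree.parents[node]
    return out


def brute_force_candidates(qedge, qnodes, operations, hierarchy):
    """Scan every operation and apply the compatibility predicate directly.

    An operation category is compatible with a query node when the node has
    no category constraint or one of the node's categories is an ancestor-
    or-equal of the operation category (checked via an upward parent walk,
    the converse of the downward expansion the planner uses).
    """

    def cat_ok(op_category, qnode):
        if not qnode.categories:
            return True
        up = ancestors_closure(hierarchy.categories, op_category)
        return any(c in up for c in qnode.categories)

    def pred_ok(op_predicate, qedge):
        if not qedge.predicates:
            return True
        up = ancestors_closure(hierarchy.predicates, op_predicate)
        return any(p in up for p in qedge.predicates)

    subject = qnodes[qedge.subject_qnode]
    obj = qnodes[qedge.object_qnode]
    out = set()
    for op in operations:
        if not pred_ok(op.predicate, qedge):
            continue
        if cat_ok(op.input_category, subject) and cat_ok(op.output_category, obj):
            out.add((op.op_id, "forward"))
        if cat_ok(op.input_category, obj) and cat_ok(op.output_category, subject):
            out.add((op.op_id, "reverse"))
    return out


def brute_force_assemble(query_graph, record_set):
    """Exhaustive enumeration of all full assignments, filtered per edge.

    Candidate entities per query node come from pinned ids and from record
    endpoints; every combination is checked against every query edge.
    """
    pair_sets = {}
    for qedge_id, qedge in query_graph.qedges.items():
        pair_sets[qedge_id] = {
            record.qedge_endpoints(qedge) for record in record_set.records(qedge_id)
        }
    candidates = {}
    for qnode_id, qnode in query_graph.qnodes.items():
        pool = set(qnode.ids)
        for qedge_id, qedge in query_graph.qedges.items():
            if qedge.subject_qnode == qnode_id:
                pool |= {s for s, _ in pair_sets[qedge_id]}
            if qedge.object_qnode == qnode_id:
                pool |= {o for _, o in pair_sets[qedge_id]}
        candidates[qnode_id] = pool
    qnode_ids = sorted(query_graph.qnodes)
    results = set()
    for combo in itertools.product(*(sorted(candidates[q]) for q in qnode_ids)):
        assignment = dict(zip(qnode_ids, combo))
        ok = all(
            (assignment[e.subject_qnode], assignment[e.object_qnode]) in pair_sets[e.qedge_id]
            for e in query_graph.qedges.values()
        )
        if ok:
            for qnode in query_graph.qnodes.values():
                if qnode.pinned and assignment[qnode.qnode_id] not in set(qnode.ids):
                    ok = False
                    break
        if ok:
            results.add(tuple(sorted((q, str(c)) for q, c in assignment.items())))
    return results


def random_registry(rng: random.Random, hierarchy, n_apis=3, n_ops=8):
    """Random annotated specs over the fixture vocabulary."""
    categories = sorted(hierarchy.categories.parents)
    predicates = sorted(hierarchy.predicates.parents)
    docs = [[] for _ in range(n_apis)]
    for i in range(n_ops):
        docs[rng.randrange(n_apis)].append(
            {
                "op_id": f"rnd{i}",
                "input_category": rng.choice(categories),
                "input_prefix": rng.choice(["MONDO", "NCBIGene", "CHEBI"]),
                "predicate": rng.choice(predicates),
                "output_category": rng.choice(categories),
                "output_prefix": rng.choice(["MONDO", "NCBIGene", "CHEBI"]),
                "request_template": "ids={inputs}",
                "response_id_path": "hits[].id",
            }
        )
    return [
        parse_api_spec(json.dumps(make_spec_doc(f"RandomAPI{j}", ops)), hierarchy)
        for j, ops in enumerate(docs)
        if ops
    ]
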