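"""Seeded synthetic API networks: offline stand-ins for a live registry.

The generator emits everything a complete engine run needs — annotated API
spec documents, per-operation association tables, an identifier-equivalence
(normalizer) table with synonym identifiers under a second prefix, a
term/pair co-occurrence table, and a miniature category/predicate hierarchy
— bundled with a manifest recording the seed and parameters. Regeneration
with the same seed is byte-identical.

It also provides a pure in-process :class:`FixtureTransport` that answers
each operation's requests from its association table in exactly the response
shape implied by the operation's declared id path, and an exhaustive
:func:`ground_truth` oracle that enumerates the correct result set directly
from the association tables, sharing no code with the planner, executor or
assembler.

The network layout is a backbone cycle over the generated categories
(category i feeds category i+1); each API contributes exactly one operation
on that backbone, assigned round-robin, so with A APIs, E entities per
category and mean out-degree d the expected number of associations is
A * E * d. Per input entity the out-neighbor count is Poisson(d), drawn
without replacement from the output category's entity pool — sparse,
realistic fan-out with an analyzable total.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import GenerationError, TransportError, UnknownOperationError
from .hierarchy import CategoryHierarchy, parse_hierarchy
from .idpath import IdPath, parse_id_path
from .query import QueryGraph
from .registry import APISpec, MetaKG, build_meta_kg, parse_api_spec

__all__ = [
    "GenerationParams",
    "NetworkBundle",
    "generate",
    "build_response",
    "FixtureTransport",
    "make_fixture_transport",
    "load_bundle",
    "ground_truth",
]

# Category names, primary identifier prefixes and synonym (alias) prefixes
# mirror common biomedical namespaces; categories beyond the pool get
# generated names.
_CATEGORY_POOL = [
    ("Disease", "MONDO", "DOID"),
    ("Gene", "NCBIGene", "ENSEMBL"),
    ("ChemicalEntity", "CHEBI", "PUBCHEM.COMPOUND"),
    ("PhenotypicFeature", "HP", "MEDDRA"),
    ("Protein", "UniProtKB", "PR"),
    ("Pathway", "REACT", "SMPDB"),
    ("BiologicalProcess", "GO", "XBP"),
    ("Cell", "CL", "XCL"),
]

_PREDICATE_POOL = [
    "condition_associated_with_gene",
    "gene_has_chemical_association",
    "interacts_with",
    "affects",
    "participates_in",
    "correlated_with",
    "coexists_with",
    "contributes_to",
]

_RESPONSE_PATHS = [
    "hits[].id",
    "data.associations[].object_id",
    "results[].target.id",
]


@dataclass(frozen=True)
class GenerationParams:
    seed: int = 0
    n_categories: int = 3
    n_apis: int = 3
    n_entities_per_category: int = 20
    mean_out_degree: float = 2.0
    fraction_of_entities_with_synonyms: float = 0.25
    failure_modes: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.n_categories < 1 or self.n_apis < 1 or self.n_entities_per_category < 1:
            raise GenerationError("counts must be positive")
        if self.mean_out_degree < 0:
            raise GenerationError("mean_out_degree must be non-negative")
        if self.mean_out_degree > self.n_entities_per_category:
            raise GenerationError(
                "infeasible parameters: mean out-degree exceeds the entity pool"
            )
        if not 0.0 <= self.fraction_of_entities_with_synonyms <= 1.0:
            raise GenerationError("fraction_of_entities_with_synonyms must be in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "n_categories": self.n_categories,
            "n_apis": self.n_apis,
            "n_entities_per_category": self.n_entities_per_category,
            "mean_out_degree": self.mean_out_degree,
            "fraction_of_entities_with_synonyms": self.fraction_of_entities_with_synonyms,
            "failure_modes": list(self.failure_modes),
        }


def _category_triple(index: int) -> tuple[str, str, str]:
    if index < len(_CATEGORY_POOL):
        return _CATEGORY_POOL[index]
    return (f"Category{index}", f"PFX{index}", f"XPFX{index}")


@dataclass
class NetworkBundle:
    """A complete offline network: specs, data tables and vocabulary."""

    params: GenerationParams
    categories: list[str]
    hierarchy_text: str
    spec_documents: list[dict[str, Any]]
    op_info: dict[str, dict[str, Any]]  # op_id -> annotation fields (plain)
    associations: dict[str, list[tuple[str, str]]]  # op_id -> (in, out) curies
    normalizer_clusters: list[dict[str, Any]]
    cooccurrence: dict[str, Any]
    manifest: dict[str, Any] = field(default_factory=dict)

    # -- typed views -------------------------------------------------------
    def hierarchy(self) -> CategoryHierarchy:
        return parse_hierarchy(self.hierarchy_text)

    def api_specs(self, hierarchy: CategoryHierarchy | None = None) -> list[APISpec]:
        hierarchy = hierarchy or self.hierarchy()
        return [
            parse_api_spec(json.dumps(doc, sort_keys=True), hierarchy)
            for doc in self.spec_documents
        ]

    def meta_kg(self) -> MetaKG:
        return build_meta_kg(self.api_specs())

    # -- persistence -------------------------------------------------------
    def write(self, directory: str | Path) -> Path:
        """Write the bundle directory (plain-text artifacts only)."""
        root = Path(directory)
        (root / "specs").mkdir(parents=True, exist_ok=True)
        (root / "data").mkdir(parents=True, exist_ok=True)
        spec_names = []
        for i, doc in enumerate(self.spec_documents):
            name = f"specs/api{i}.json"
            spec_names.append(name)
            (root / name).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        for op_id, rows in sorted(self.associations.items()):
            lines = "".join(f"{a}\t{b}\n" for a, b in rows)
            (root / "data" / f"{op_id}.tsv").write_text(lines)
        (root / "normalizer.json").write_text(
            json.dumps(self.normalizer_clusters, indent=2, sort_keys=True) + "\n"
        )
        (root / "cooccurrence.json").write_text(
            json.dumps(self.cooccurrence, indent=2, sort_keys=True) + "\n"
        )
        (root / "hierarchy.txt").write_text(self.hierarchy_text)
        (root / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )
        (root / "config.json").write_text(
            json.dumps(
                {
                    "specs": spec_names,
                    "hierarchy": "hierarchy.txt",
                    "normalizer": "normalizer.json",
                    "cooccurrence": "cooccurrence.json",
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        return root


def _make_hierarchy_text(categories: list[str], predicates: list[str]) -> str:
    lines = ["NamedThing\t-"]
    lines += [f"{c}\tNamedThing" for c in categories]
    lines.append("#predicates")
    lines.append("related_to\t-")
    lines += [f"{p}\trelated_to" for p in sorted(set(predicates))]
    return "\n".join(lines) + "\n"


def generate(params: GenerationParams) -> NetworkBundle:
    """Generate a complete seeded network bundle; see module docstring."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    K = params.n_categories
    E = params.n_entities_per_category

    triples = [_category_triple(i) for i in range(K)]
    categories = [t[0] for t in triples]
    prefix_of = {t[0]: t[1] for t in triples}
    alt_prefix_of = {t[0]: t[2] for t in triples}

    # entity pools: canonical curies per category, plus synonym aliases
    entities: dict[str, list[str]] = {}
    clusters: list[dict[str, Any]] = []
    for cat in categories:
        pool = [f"{prefix_of[cat]}:{1000 + i}" for i in range(E)]
        entities[cat] = pool
        has_alias = rng.random(E) < params.fraction_of_entities_with_synonyms
        for i, curie in enumerate(pool):
            equivalents = (
                [f"{alt_prefix_of[cat]}:{9000 + i}"] if bool(has_alias[i]) else []
            )
            clusters.append(
                {
                    "canonical": curie,
                    "category": cat,
                    "label": f"{cat} {1000 + i}",
                    "equivalents": equivalents,
                }
            )

    # one backbone operation per API, round-robin over consecutive pairs
    spec_documents: list[dict[str, Any]] = []
    op_info: dict[str, dict[str, Any]] = {}
    associations: dict[str, list[tuple[str, str]]] = {}
    predicates_used: list[str] = []
    for j in range(params.n_apis):
        pair = j % K
        in_cat = categories[pair]
        out_cat = categories[(pair + 1) % K]
        predicate = _PREDICATE_POOL[pair % len(_PREDICATE_POOL)]
        predicates_used.append(predicate)
        op_id = f"api{j}_op0"
        info = {
            "op_id": op_id,
            "method": "GET",
            "input_category": in_cat,
            "input_prefix": prefix_of[in_cat],
            "predicate": predicate,
            "output_category": out_cat,
            "output_prefix": prefix_of[out_cat],
            "request_template": "ids={inputs}",
            "response_id_path": _RESPONSE_PATHS[j % len(_RESPONSE_PATHS)],
            "max_batch": 50,
        }
        op_info[op_id] = dict(info, api_name=f"SyntheticAPI{j}")
        spec_documents.append(
            {
                "info": {"title": f"SyntheticAPI{j}", "version": "1.0"},
                "servers": [{"url": f"https://api{j}.example.org"}],
                "paths": {"/query": {"x-kg-operations": [info]}},
            }
        )
        out_pool = entities[out_cat]
        rows: list[tuple[str, str]] = []
        for input_curie in entities[in_cat]:
            k = int(min(rng.poisson(params.mean_out_degree), len(out_pool)))
            if k:
                chosen = rng.choice(len(out_pool), size=k, replace=False)
                rows.extend((input_curie, out_pool[int(c)]) for c in sorted(chosen))
        associations[op_id] = rows

    for op_id in params.failure_modes:
        if op_id not in op_info:
            raise GenerationError(f"failure mode names unknown operation {op_id!r}")

    # co-occurrence counts derived from the association adjacency:
    # f(x) = degree(x) + 1, f2(x, y) = shared-edge indicator + count of
    # shared neighbors, N = 10 * total entities. Satisfies all table
    # invariants and gives non-degenerate NGD values.
    neighbors: dict[str, set[str]] = {c: set() for pool in entities.values() for c in pool}
    for rows in associations.values():
        for a, b in rows:
            if a != b:
                neighbors[a].add(b)
                neighbors[b].add(a)
    all_entities = sorted(neighbors)
    terms = {x: len(neighbors[x]) + 1 for x in all_entities}
    pairs = []
    for x, y in itertools.combinations(all_entities, 2):
        f2 = int(y in neighbors[x]) + len(neighbors[x] & neighbors[y])
        if f2 > 0:
            pairs.append([x, y, f2])
    cooccurrence = {"N": 10 * len(all_entities), "terms": terms, "pairs": pairs}

    hierarchy_text = _make_hierarchy_text(categories, predicates_used)
    bundle = NetworkBundle(
        params=params,
        categories=categories,
        hierarchy_text=hierarchy_text,
        spec_documents=spec_documents,
        op_info=op_info,
        associations=associations,
        normalizer_clusters=clusters,
        cooccurrence=cooccurrence,
        manifest={
            "generator": "fedkg.synthetic",
            "params": params.to_dict(),
            "counts": {
                "categories": K,
                "apis": params.n_apis,
                "entities": len(all_entities),
                "associations": sum(len(r) for r in associations.values()),
            },
        },
    )
    return bundle


# ---------------------------------------------------------------------------
# fixture transport


def build_response(path: IdPath | str, output_ids: list[str]) -> Any:
    """Build the smallest response document whose id-path extraction yields
    exactly ``output_ids`` in order.

    The array segment of the path (the generator always declares exactly
    one) carries one element per output id; array segments before the last
    one become singleton lists.
    """
    if isinstance(path, str):
        path = parse_id_path(path)
    segments = path.segments
    array_positions = [i for i, s in enumerate(segments) if s.is_array]
    if not array_positions:
        if len(output_ids) > 1:
            raise TransportError(
                f"path {path} has no array segment and cannot carry {len(output_ids)} ids"
            )
        doc: Any = output_ids[0] if output_ids else None
        for segment in reversed(segments):
            doc = {segment.key: doc}
        return doc
    last = array_positions[-1]
    tail = segments[last + 1 :]

    def leaf(output_id: str) -> Any:
        node: Any = output_id
        for segment in reversed(tail):
            node = {segment.key: node}
        return node

    doc = [leaf(o) for o in output_ids]
    for i in range(last, -1, -1):
        segment = segments[i]
        if segment.is_array and i != last:
            doc = {segment.key: [doc]}
        elif segment.is_array:
            doc = {segment.key: doc}
        else:
            doc = {segment.key: doc}
    return doc


class FixtureTransport:
    """Pure in-process transport answering from association tables.

    Same request, same response — no state, no retries. Operations listed
    as failing raise :class:`TransportError` (a simulated outage), and a
    request for an operation the transport does not know raises
    :class:`UnknownOperationError`, which is distinguishable from an empty
    result.
    """

    def __init__(
        self,
        response_paths: dict[str, str],
        tables: dict[str, list[tuple[str, str]]],
        failing: set[str] = frozenset(),
    ) -> None:
        self._paths = dict(response_paths)
        self._failing = set(failing)
        self._index: dict[str, dict[str, list[str]]] = {}
        for op_id, rows in tables.items():
            index: dict[str, list[str]] = {}
            for input_curie, output_curie in rows:
                input_local = input_curie.split(":", 1)[1]
                output_local = output_curie.split(":", 1)[1]
                index.setdefault(input_local, []).append(output_local)
            self._index[op_id] = index
        self.calls = 0

    def call(self, request) -> Any:
        if request.op_id not in self._paths:
            raise UnknownOperationError(f"fixture transport knows no operation {request.op_id!r}")
        if request.op_id in self._failing:
            raise TransportError(f"operation {request.op_id!r} is down (simulated outage)")
        self.calls += 1
        index = self._index.get(request.op_id, {})
        outputs: list[str] = []
        for input_local in request.inputs:
            outputs.extend(index.get(input_local, []))
        return build_response(self._paths[request.op_id], outputs)


def make_fixture_transport(bundle: NetworkBundle) -> FixtureTransport:
    return FixtureTransport(
        response_paths={
            op_id: info["response_id_path"] for op_id, info in bundle.op_info.items()
        },
        tables=bundle.associations,
        failing=set(bundle.params.failure_modes),
    )


def load_bundle(directory: str | Path) -> NetworkBundle:
    """Read a bundle directory previously written by :meth:`NetworkBundle.write`."""
    root = Path(directory)
    manifest = json.loads((root / "manifest.json").read_text())
    params = GenerationParams(
        **{
            **manifest["params"],
            "failure_modes": tuple(manifest["params"].get("failure_modes", ())),
        }
    )
    spec_documents = [
        json.loads(p.read_text()) for p in sorted((root / "specs").glob("*.json"))
    ]
    op_info: dict[str, dict[str, Any]] = {}
    for doc in spec_documents:
        for path_item in doc.get("paths", {}).values():
            for block in path_item.get("x-kg-operations", []):
                op_info[block["op_id"]] = dict(block, api_name=doc["info"]["title"])
    associations = {}
    for table in sorted((root / "data").glob("*.tsv")):
        rows = []
        for line in table.read_text().splitlines():
            if line.strip():
                a, b = line.split("\t")
                rows.append((a, b))
        associations[table.stem] = rows
    return NetworkBundle(
        params=params,
        categories=[],
        hierarchy_text=(root / "hierarchy.txt").read_text(),
        spec_documents=spec_documents,
        op_info=op_info,
        associations=associations,
        normalizer_clusters=json.loads((root / "normalizer.json").read_text()),
        cooccurrence=json.loads((root / "cooccurrence.json").read_text()),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# ground-truth oracle


def ground_truth(
    bundle: NetworkBundle,
    query_graph: QueryGraph,
    include_failing: bool = False,
) -> set[tuple[tuple[str, str], ...]]:
    """Exhaustively enumerate the correct result set for a query.

    Works directly on the bundle's association tables and normalizer
    clusters — independent of the planner, executor and assembler — and
    returns the set of node-binding keys ``((qnode_id, curie), ...)``. Ops
    marked as failing are excluded unless ``include_failing`` is set, since
    an engine honoring error isolation can only see healthy operations.
    """
    hierarchy = bundle.hierarchy()
    canonical: dict[str, str] = {}
    for cluster in bundle.normalizer_clusters:
        canonical[cluster["canonical"]] = cluster["canonical"]
        for equivalent in cluster.get("equivalents", []):
            canonical[equivalent] = cluster["canonical"]

    def canon(curie: str) -> str:
        return canonical.get(curie, curie)

    failing = set() if include_failing else set(bundle.params.failure_modes)

    def category_ok(op_category: str, wanted: tuple[str, ...]) -> bool:
        return not wanted or any(
            w in hierarchy.categories and op_category in hierarchy.descendants(w)
            for w in wanted
        )

    def predicate_ok(op_predicate: str, wanted: tuple[str, ...]) -> bool:
        return not wanted or any(
            w in hierarchy.predicates and op_predicate in hierarchy.predicate_descendants(w)
            for w in wanted
        )

    # supporting (subject, object) canonical pairs per qedge
    pair_sets: dict[str, set[tuple[str, str]]] = {}
    for qedge_id, qedge in query_graph.qedges.items():
        subject_node = query_graph.qnodes[qedge.subject_qnode]
        object_node = query_graph.qnodes[qedge.object_qnode]
        pairs: set[tuple[str, str]] = set()
        for op_id, info in bundle.op_info.items():
            if op_id in failing:
                continue
            if not predicate_ok(info["predicate"], qedge.predicates):
                continue
            rows = bundle.associations.get(op_id, [])
            if category_ok(info["input_category"], subject_node.categories) and category_ok(
                info["output_category"], object_node.categories
            ):
                pairs.update((canon(a), canon(b)) for a, b in rows)
            if category_ok(info["input_category"], object_node.categories) and category_ok(
                info["output_category"], subject_node.categories
            ):
                pairs.update((canon(b), canon(a)) for a, b in rows)
        pair_sets[qedge_id] = pairs

    pinned: dict[str, set[str]] = {
        n.qnode_id: {canon(str(c)) for c in n.ids}
        for n in query_graph.qnodes.values()
        if n.pinned
    }

    if not query_graph.qedges:
        return {
            ((qnode_id, entity),)
            for qnode_id, entities in pinned.items()
            for entity in entities
        }

    # candidate entities per qnode: pinned ids, or any entity occurring at
    # that position in every incident qedge's pair set
    candidates: dict[str, set[str]] = {}
    for qnode_id, qnode in query_graph.qnodes.items():
        if qnode_id in pinned:
            candidates[qnode_id] = pinned[qnode_id]
            continue
        pools = []
        for qedge in query_graph.qedges.values():
            if qedge.subject_qnode == qnode_id:
                pools.append({s for s, _ in pair_sets[qedge.qedge_id]})
            if qedge.object_qnode == qnode_id:
                pools.append({o for _, o in pair_sets[qedge.qedge_id]})
        candidates[qnode_id] = set.intersection(*pools) if pools else set()

    qnode_ids = sorted(query_graph.qnodes)
    results: set[tuple[tuple[str, str], ...]] = set()
    for combo in itertools.product(*(sorted(candidates[q]) for q in qnode_ids)):
        assignment = dict(zip(qnode_ids, combo))
        if all(
            (assignment[e.subject_qnode], assignment[e.object_qnode]) in pair_sets[e.qedge_id]
            for e in query_graph.qedges.values()
        ):
            results.add(tuple(sorted(assignment.items())))
    return results
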