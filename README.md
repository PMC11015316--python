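# fedkg — query engine for a federated biomedical knowledge graph of APIs

Biomedical knowledge is scattered across many web APIs that disagree on
identifiers, response shapes and vocabulary. `fedkg` treats a collection of
*semantically annotated* APIs as one virtual, federated knowledge graph: each
API endpoint is annotated with the semantic category and identifier prefix of
its inputs and outputs, the predicate of the association it serves, and the
path to output identifiers in its response. The union of these annotations
forms a **meta-knowledge graph** (meta-KG) — nodes are categories such as
`Disease`, `Gene`, `ChemicalEntity`; edges are API operations linking two
categories via a predicate — and multi-hop graph questions are answered by
traversing it at query time, with no centralized graph to build or maintain.

A question is posed as a TRAPI-style **query graph**: pinned nodes carry
known CURIEs (`MONDO:0005148`), open nodes carry category constraints, edges
carry optional predicate constraints. The engine answers it in three phases:

1. **Query-path planning** — for every query edge, find all compatible
   operations in the meta-KG (categories and predicates expanded through a
   miniature Biolink-style hierarchy, in both the forward and reverse
   retrieval direction) and fix an execution order that chains hops outward
   from the pinned nodes.
2. **Query-path execution** — render each operation's request template for
   the entities bound at the edge's input side, call the API through a
   pluggable transport, extract output identifiers via the operation's
   declared id path, and canonicalize both endpoints through a local
   identifier-equivalence table (so an NCBI gene id and an Ensembl gene id
   chain correctly across APIs). Failing operations are isolated: they log a
   warning and the rest of the plan still contributes.
3. **Integration and scoring** — join the per-edge records into result
   sub-graphs matching the query topology and score each result by a
   composite of record support, path length, and semantic similarity between
   adjacent entities derived from the Normalized Google Distance

   `NGD(x,y) = (max(log f(x), log f(y)) − log f(x,y)) / (log N − min(log f(x), log f(y)))`

   computed over a local term/pair co-occurrence table.

Everything external is substitutable and offline-testable: live APIs are
replaced by a transport contract (with an in-process fixture transport), the
node-normalizer service by a local equivalence table, and the Biolink Model
by a miniature category/predicate hierarchy file. A seeded synthetic-network
generator produces complete bundles — annotated specs, association tables,
normalizer, co-occurrence counts, hierarchy — together with an independent
brute-force ground-truth oracle.

## Worked example

```bash
python examples/two_hop_query.py
```

prints (seed 7):

```
network: {'categories': 3, 'apis': 3, 'entities': 60, 'associations': 107}
pinned start entity: MONDO:1000
plan: edges in order ['e0', 'e1'], candidates per edge {'e0': 1, 'e1': 1}
2 results (ranked by composite score):
  MONDO:1000 -> NCBIGene:1007 -> CHEBI:1005  score=0.630 (records=2, mean hop distance=1.5, co-occurrence sim=0.701)
  MONDO:1000 -> NCBIGene:1008 -> CHEBI:1006  score=0.592 (records=2, mean hop distance=1.5, co-occurrence sim=0.585)
```

Starting from the pinned disease `MONDO:1000`, the planner found one
candidate operation per hop, execution retrieved the disease's genes and
then those genes' chemicals, and assembly produced two complete
disease→gene→chemical sub-graphs. Each is supported by 2 records, its open
nodes sit 1 and 2 hops from the pin (mean 1.5), and the first result ranks
higher because its entities co-occur more strongly in the corpus counts.

Other examples: `examples/build_metakg.py` (annotation dialect and meta-KG
summary), `examples/identifier_translation.py` (CURIE equivalence and prefix
translation), `examples/ngd_scoring.py` (NGD and the score components).

## Command line

A thin CLI wraps the same library calls:

```bash
fedkg fixture --seed 7 --out net/                  # write a synthetic bundle
fedkg metakg  --config net/config.json             # meta-KG summary (--export for node-link JSON)
fedkg query   --config net/config.json --query q.json --out r.json [--dump-plan p.json]
```

Exit codes: 0 success (including empty results), 2 invalid input or
configuration, 3 unplannable query.

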