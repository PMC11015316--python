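# Methods

## The model

`fedkg` answers multi-hop graph questions over a *virtual* knowledge graph
that is never materialized: the graph exists only as a set of web APIs whose
endpoints are annotated with semantic metadata. An annotation (one
"operation") states the input category and identifier prefix, the predicate,
the output category and prefix, a request template with an `{inputs}`
placeholder, and the path to output identifiers in the response document.
The operations jointly induce the meta-knowledge graph over categories; a
query is answerable exactly when each of its edges maps onto at least one
meta-KG edge compatible with its constraints.

The assumptions this rests on:

* annotations are truthful — an operation declared `Disease → Gene` with
  predicate *p* really serves associations of that shape;
* identifier equivalence is supplied externally (a normalizer table) and is
  transitive within a cluster with a unique canonical member;
* categories and predicates form single-inheritance trees. Real-world
  vocabularies use multiple inheritance; the single-parent restriction keeps
  descendant computations unambiguous and the file format trivial, at the
  cost of not expressing categories with two parents.

## Matching and planning

Compatibility is *descendant-or-equal*: an operation category matches a
query-node category when it is the same token or below it in the tree, and
likewise for predicates. Ancestors deliberately do not match — an
unconstrained `NamedThing`-serving operation would otherwise attach to every
edge and fan out to every API. Unconstrained nodes/edges match everything.
Every edge is matched in both directions: an operation whose input sits on
the edge's object side is planned as `reverse` and its retrieved pairs are
bound to the edge flipped. Predicate inversion vocabularies are not applied
when executing in reverse; the annotated predicate is matched verbatim. This
is a known divergence risk against systems that maintain inverse-predicate
tables, and it is surfaced here rather than hidden.

Edge ordering is breadth-first from the pinned nodes with ties broken by
ascending qedge id. Any order satisfying "each edge touches an already-bound
node" is correct; breadth-first with a lexicographic tie-break makes plans
deterministic, which golden-file tests and byte-identical reruns rely on.

## Execution

The input set of an edge is the union of canonicalized pinned identifiers
and the entities produced at the shared node by earlier edges. For each
candidate operation, inputs are translated to the operation's declared
prefix via the normalizer's equivalence clusters before prefix filtering;
entities with no equivalent under that prefix are skipped for that operation
(logged at debug level). Unknown identifiers pass through un-normalized but
flagged instead of being dropped — federated sources disagree, and a
pass-through record is more informative than a silent hole.

Request rendering chunks inputs into ⌈n/max_batch⌉ requests (`max_batch`
defaults to 100). The engine itself, however, issues one request per input
entity: the response dialect is a bare id path (`hits[].id`) that does not
echo inputs, so a batched response cannot attribute an output id to the
input that produced it, and sound multi-hop joins require that attribution.
Batch rendering remains available for callers whose response schema does
echo inputs. The id-path dialect is intentionally minimal — dot-separated
keys, `[]` mapping over arrays, missing keys yielding no results — because a
fully specifiable dialect is testable end to end, unlike general JSONPath.

Operations fail independently: a transport error marks the operation failed
for that edge, logs a warning, and execution continues with the remaining
candidates. An edge whose candidates all fail yields an empty record set,
not an aborted query.

## Assembly and scoring

Assembly enumerates exactly the assignments of concrete entities to query
nodes for which every query edge has at least one supporting record,
deduplicating on node bindings and merging edge bindings. The join processes
edges in a connectivity-preserving order and extends partial assignments by
the (subject, object) pairs supported on each edge; with the instance sizes
the engine targets (≤5 query nodes, hundreds of records) this is exact, and
it is verified against an independent exhaustive enumerator.

Each result is scored as

    total = w_paths · g(n) + w_length · h(L) + w_sim · sim

with `g(n) = 1 − 1/(1 + ln(1+n))` over the number of distinct supporting
records n (distinct provenance counts separately — two APIs reporting the
same association are two pieces of evidence), `h(L) = 1/L` over the mean
shortest hop distance L of the open nodes from the nearest pinned node, and
`sim` the mean of `max(0, 1 − NGD/ngd_cap)` over entity pairs adjacent in
the result. Defaults: equal weights (⅓ each, normalized on construction) and
`ngd_cap = 1` (distance at which similarity saturates to zero). All three
components lie in [0, 1], so the total does too; it is monotone in support
and anti-monotone in any pairwise NGD. Pairs with terms absent from the
co-occurrence table are skipped; a result with no computable pair gets
`sim = 0`. For a query with no open nodes, L is defined as 1. Scores are
comparable within one query only; no cross-query normalization is applied.
Ranking is by descending total with lexicographic node-binding tie-break,
making output order permutation-invariant.

The NGD formula is the standard published form. A term's joint count with
itself defaults to its own occurrence count when not explicitly stored, so
self-distance is exactly 0; a zero joint count gives +∞ (similarity 0); a
non-positive denominator (a term as frequent as the corpus) gives +∞ unless
the numerator is 0.

## The synthetic network

The generator emulates a small federated API ecosystem: K categories with
realistic prefix pairs (MONDO/DOID, NCBIGene/ENSEMBL, ...), E entities per
category, and one operation per API laid round-robin on the backbone cycle
category\_i → category\_{i+1 mod K}, each with its own predicate, request
template and response shape (three id-path dialect shapes are rotated).
Per input entity, out-neighbors are drawn without replacement with count
~ Poisson(d), so a bundle with A APIs has an expected A·E·d associations.
Defaults — K = 3, A = 3, E = 20, d = 2, synonym fraction 0.25 — give a
network where a two-hop query from a typical pinned entity returns a
handful of results: large enough to exercise joins and ranking, small
enough that the exhaustive oracle is instant. A fraction of entities get
one alias under the category's secondary prefix, wired into the normalizer
table; generated operations use primary prefixes, and the translation path
is exercised by alias-pinned queries. Co-occurrence counts are synthesized
from the association adjacency (`f(x) = degree+1`,
`f2(x,y) = shared-edge + shared-neighbor count`, `N = 10·entities`), which
provably satisfies the table invariants and yields non-degenerate NGD
values.

What the generator does *not* emulate: real response schemas beyond the
declared id path, latency and rate limits, inconsistent or stale data
across sources, multi-predicate endpoints, and hub-like degree
distributions. Passing tests therefore demonstrate the engine's logic —
planning, chaining, translation, assembly, scoring — not robustness to the
messiness of production APIs.

All randomness flows through one seeded NumPy generator; a bundle is a pure
function of its parameters, and written bundles are byte-identical across
regenerations (sorted-key JSON, ordered TSV).

## Verification strategy and problem sizes

Three oracles are kept code-independent of the paths they check: a
brute-force registry scan using upward ancestor walks (the planner expands
downward), an exhaustive assignment enumerator over record endpoints, and a
ground-truth enumerator working directly on the bundle's association tables
and normalizer clusters. The standing verification run uses 200 random
(registry, edge) fixtures for the planner, 100 random instances (≤5 query
nodes, ≤200 records) for the assembler, and 20 seeded bundles (12 entities
per category) for end-to-end equality with byte-identical repeats — sizes at
which exhaustive enumeration is exact and the whole run takes seconds.

## Known limitations

* One predicate per operation; endpoints serving several predicates need
  one annotation each.
* No cost-based plan optimization, caching, or rate-limit scheduling; edges
  are executed sequentially in plan order.
* Cyclic query graphs are accepted and handled by the join semantics, but
  only tree-plus-chord topologies are exercised by the test corpus.
* Whole-graph analytics (centrality, embeddings) are out of scope by
  design: the federated graph is never instantiated in one place.
* The HTTP transport adapter is minimal (stdlib, single timeout, no
  retries) and is not exercised against live services in the test suite.
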