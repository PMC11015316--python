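"""Build a meta-knowledge graph from annotated API specs and summarize it.

Two toy specs are annotated inline: one API serving disease->gene
associations and one serving gene->chemical associations. The meta-KG's
nodes are semantic categories and each edge is one API operation; the
summary counts how many distinct APIs can retrieve each kind of
association.
"""

import json

from fedkg import build_meta_kg, meta_kg_summary, parse_api_spec, parse_hierarchy

HIERARCHY = """\
NamedThing\t-
Disease\tNamedThing
Gene\tNamedThing
ChemicalEntity\tNamedThing
#predicates
related_to\t-
condition_associated_with_gene\trelated_to
gene_has_chemical_association\trelated_to
"""

DISEASE_GENE_API = {
    "info": {"title": "Disease-Gene API", "version": "1.0"},
    "servers": [{"url": "https://disease-gene.example.org"}],
    "paths": {
        "/associations": {
            "x-kg-operations": [
                {
                    "op_id": "dg_forward",
                    "method": "GET",
                    "input_category": "Disease",
                    "input_prefix": "MONDO",
                    "predicate": "condition_associated_with_gene",
                    "output_category": "Gene",
                    "output_prefix": "NCBIGene",
                    "request_template": "disease_ids={inputs}",
                    "response_id_path": "hits[].gene_id",
                }
            ]
        }
    },
}

GENE_CHEMICAL_API = {
    "info": {"title": "Gene-Chemical API", "version": "2.3"},
    "servers": [{"url": "https://gene-chem.example.org"}],
    "paths": {
        "/query": {
            "x-kg-operations": [
                {
                    "op_id": "gc_forward",
                    "method": "POST",
                    "input_category": "Gene",
                    "input_prefix": "NCBIGene",
                    "predicate": "gene_has_chemical_association",
                    "output_category": "ChemicalEntity",
                    "output_prefix": "CHEBI",
                    "request_template": '{"genes": "{inputs}"}',
                    "response_id_path": "results[].chemical.id",
                }
            ]
        }
    },
}

hierarchy = parse_hierarchy(HIERARCHY)
specs = [
    parse_api_spec(json.dumps(doc), hierarchy)
    for doc in (DISEASE_GENE_API, GENE_CHEMICAL_API)
]
kg = build_meta_kg(specs)

print(f"meta-KG: {len(kg.categories)} categories, {len(kg.edges)} edges")
for row in meta_kg_summary(kg):
    print(
        f"  {row['subject_category']:>14} -> {row['object_category']:<14} "
        f"{row['n_apis']} API(s), {row['n_operations']} operation(s)"
    )
# Each printed row is one traversable hop: a two-hop disease->gene->chemical
# query is answerable because the first row's object category matches the
# second row's subject category.
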