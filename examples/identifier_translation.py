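"""Identifier translation: equivalent CURIEs resolve to one canonical entity.

Federated APIs disagree about identifier namespaces (one serves NCBI gene
ids, another Ensembl ids). The normalizer table maps every member of an
equivalence cluster to a canonical identifier, and the executor uses the
cluster's equivalents to translate an input into whatever prefix an
operation expects — so a query pinned with an alias returns exactly the
same results as one pinned with the canonical form.
"""

from fedkg import NormalizerTable, parse_curie

clusters = [
    {
        "canonical": "NCBIGene:7157",
        "category": "Gene",
        "label": "TP53",
        "equivalents": ["ENSEMBL:ENSG00000141510", "HGNC:11998"],
    },
]
table = NormalizerTable(clusters)

for text in ("ENSEMBL:ENSG00000141510", "HGNC:11998", "NCBIGene:7157", "UMLS:C0079419"):
    entity = table.normalize(parse_curie(text))
    status = "canonical" if entity.normalized else "unknown (passed through)"
    print(f"{text:>28} -> {entity.curie}  [{entity.label}, {status}]")

alias = table.alias_with_prefix(parse_curie("NCBIGene:7157"), "ENSEMBL")
print(f"\nENSEMBL-speaking API gets: {alias}")
# The first three inputs land on the same canonical gene; the unknown CURIE
# passes through flagged rather than being dropped, and the alias lookup is
# what lets the executor call an API that only understands Ensembl ids.
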