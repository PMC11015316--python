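"""Shared handcrafted fixtures: a three-API registry over a miniature
vocabulary, association tables, a normalizer table and co-occurrence counts.

The layout mirrors a classic disease -> gene -> chemical two-hop scenario:
two APIs (a CTD-like one and a Monarch-like one) serve disease-gene
associations and one (MyChem-like) serves gene-chemical associations.
"""

import json

import pytest

from fedkg.executor import NormalizerTable
from fedkg.hierarchy import parse_hierarchy
from fedkg.query import parse_query_graph
from fedkg.registry import build_meta_kg, parse_api_spec
from fedkg.scoring import CooccurrenceTable
from fedkg.synthetic import FixtureTransport

HIERARCHY_TEXT = """\
NamedThing\t-
Disease\tNamedThing
Gene\tNamedThing
ChemicalEntity\tNamedThing
SmallMolecule\tChemicalEntity
#predicates
related_to\t-
condition_associated_with_gene\trelated_to
affects\trelated_to
gene_has_chemical_association\taffects
"""


def make_spec_doc(title, ops):
    paths = {}
    for op in ops:
        paths.setdefault(op.pop("path", "/query"), {"x-kg-operations": []})[
            "x-kg-operations"
        ].append(op)
    return {
        "info": {"title": title, "version": "1.0"},
        "servers": [{"url": f"https://{title.lower().replace(' ', '-')}.example.org"}],
        "paths": paths,
    }


CTD_SPEC = make_spec_doc(
    "CTD-like API",
    [
        {
            "op_id": "ctd_disease_gene",
            "method": "GET",
            "input_category": "Disease",
            "input_prefix": "MONDO",
            "predicate": "condition_associated_with_gene",
            "output_category": "Gene",
            "output_prefix": "NCBIGene",
            "request_template": "disease_ids={inputs}",
            "response_id_path": "hits[].gene_id",
            "max_batch": 10,
        }
    ],
)

MONARCH_SPEC = make_spec_doc(
    "Monarch-like API",
    [
        {
            "op_id": "monarch_disease_gene",
            "method": "POST",
            "input_category": "Disease",
            "input_prefix": "MONDO",
            "predicate": "condition_associated_with_gene",
            "output_category": "Gene",
            "output_prefix": "NCBIGene",
            "request_template": '{"ids": "{inputs}"}',
            "response_id_path": "data.associations[].object.id",
            "max_batch": 5,
        }
    ],
)

MYCHEM_SPEC = make_spec_doc(
    "MyChem-like API",
    [
        {
            "op_id": "mychem_gene_chemical",
            "method": "GET",
            "input_category": "Gene",
            "input_prefix": "NCBIGene",
            "predicate": "gene_has_chemical_association",
            "output_category": "ChemicalEntity",
            "output_prefix": "CHEBI",
            "request_template": "gene_ids={inputs}",
            "response_id_path": "results[].id",
            "max_batch": 10,
        }
    ],
)

# associations served by the fixture transport (full CURIEs)
ASSOCIATIONS = {
    "ctd_disease_gene": [
        ("MONDO:0005148", "NCBIGene:1017"),
        ("MONDO:0005148", "NCBIGene:7157"),
        ("MONDO:0000001", "NCBIGene:9999"),
    ],
    "monarch_disease_gene": [
        ("MONDO:0005148", "NCBIGene:1017"),
    ],
    "mychem_gene_chemical": [
        ("NCBIGene:1017", "CHEBI:15365"),
        ("NCBIGene:1017", "CHEBI:6801"),
    ],
}

RESPONSE_PATHS = {
    "ctd_disease_gene": "hits[].gene_id",
    "monarch_disease_gene": "data.associations[].object.id",
    "mychem_gene_chemical": "results[].id",
}

NORMALIZER_CLUSTERS = [
    {"canonical": "MONDO:0005148", "category": "Disease", "label": "type 2 diabetes",
     "equivalents": ["DOID:9352"]},
    {"canonical": "MONDO:0000001", "category": "Disease", "label": "disease",
     "equivalents": []},
    {"canonical": "NCBIGene:1017", "category": "Gene", "label": "CDK2",
     "equivalents": ["ENSEMBL:ENSG00000123374"]},
    {"canonical": "NCBIGene:7157", "category": "Gene", "label": "TP53",
     "equivalents": ["ENSEMBL:ENSG00000141510"]},
    {"canonical": "NCBIGene:9999", "category": "Gene", "label": "GENE9999",
     "equivalents": []},
    {"canonical": "CHEBI:15365", "category": "ChemicalEntity", "label": "aspirin",
     "equivalents": []},
    {"canonical": "CHEBI:6801", "category": "ChemicalEntity", "label": "metformin",
     "equivalents": []},
]

COOCCURRENCE = {
    "N": 1000,
    "terms": {
        "MONDO:0005148": 100,
        "NCBIGene:1017": 50,
        "NCBIGene:7157": 40,
        "CHEBI:15365": 25,
        "CHEBI:6801": 10,
    },
    "pairs": [
        ["MONDO:0005148", "NCBIGene:1017", 25],
        ["MONDO:0005148", "NCBIGene:7157", 5],
        ["NCBIGene:1017", "CHEBI:15365", 10],
    ],
}

FIG2_QUERY = {
    "message": {
        "query_graph": {
            "nodes": {
                "n0": {"ids": ["MONDO:0005148"], "categories": ["Disease"]},
                "n1": {"categories": ["Gene"]},
                "n2": {"categories": ["ChemicalEntity"]},
            },
            "edges": {
                "e0": {"subject": "n0", "object": "n1",
                       "predicates": ["condition_associated_with_gene"]},
                "e1": {"subject": "n1", "object": "n2"},
            },
        }
    }
}


@pytest.fixture(scope="session")
def hierarchy():
    return parse_hierarchy(HIERARCHY_TEXT)


@pytest.fixture(scope="session")
def api_specs(hierarchy):
    return [
        parse_api_spec(json.dumps(doc), hierarchy)
        for doc in (CTD_SPEC, MONARCH_SPEC, MYCHEM_SPEC)
    ]


@pytest.fixture(scope="session")
def meta_kg(api_specs):
    return build_meta_kg(api_specs)


@pytest.fixture()
def transport():
    return FixtureTransport(response_paths=RESPONSE_PATHS, tables=ASSOCIATIONS)


@pytest.fixture(scope="session")
def normalizer():
    return NormalizerTable(NORMALIZER_CLUSTERS)


@pytest.fixture(scope="session")
def cooccurrence():
    return CooccurrenceTable.from_dict(COOCCURRENCE)


@pytest.fixture()
def fig2_query():
    return parse_query_graph(FIG2_QUERY)
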