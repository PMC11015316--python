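"""Registry of semantically annotated APIs and the meta-knowledge graph.

Each API is described by an OpenAPI-style document extended with
``x-kg-operations`` blocks: one block per retrieval direction of an endpoint,
stating the semantic category and identifier prefix of the input, the
predicate of the association served, the category/prefix of the output, a
request template with an ``{inputs}`` placeholder and the path to output
identifiers in the response. The union of all operations across the
configured specs forms the meta-knowledge graph (meta-KG): a graph whose
nodes are semantic categories and whose edges are operations connecting a
subject category to an object category via a predicate. Query planning is a
traversal of this meta-KG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import RegistryError, SpecValidationError
from .hierarchy import CategoryHierarchy, load_hierarchy
from .idpath import IdPath, parse_id_path

__all__ = [
    "OperationAnnotation",
    "APISpec",
    "RegistryConfig",
    "MetaEdge",
    "MetaKG",
    "parse_api_spec",
    "load_api_spec",
    "serialize_api_spec",
    "build_meta_kg",
    "meta_kg_summary",
    "load_registry",
]

_METHODS = ("GET", "POST")
_REQUIRED_OP_FIELDS = (
    "op_id",
    "input_category",
    "input_prefix",
    "predicate",
    "output_category",
    "output_prefix",
    "request_template",
    "response_id_path",
)

DEFAULT_MAX_BATCH = 100


@dataclass(frozen=True)
class OperationAnnotation:
    """One semantically annotated API endpoint direction."""

    op_id: str
    api_name: str
    server_url: str
    path: str
    method: str
    input_category: str
    input_prefix: str
    output_category: str
    output_prefix: str
    predicate: str
    request_template: str
    response_id_path: IdPath
    max_batch: int = DEFAULT_MAX_BATCH


@dataclass(frozen=True)
class APISpec:
    api_name: str
    title: str
    version: str
    server_url: str
    operations: tuple[OperationAnnotation, ...]


@dataclass(frozen=True)
class RegistryConfig:
    """Instance configuration: which specs to load and where the tables live."""

    spec_paths: tuple[Path, ...]
    hierarchy_path: Path
    normalizer_path: Path
    cooccurrence_path: Path

    @classmethod
    def load(cls, path: str | Path) -> "RegistryConfig":
        path = Path(path)
        try:
            raw = json.loads(path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise RegistryError(f"cannot read registry config {path}: {exc}") from exc
        base = path.parent
        try:
            cfg = cls(
                spec_paths=tuple(base / p for p in raw["specs"]),
                hierarchy_path=base / raw["hierarchy"],
                normalizer_path=base / raw["normalizer"],
                cooccurrence_path=base / raw["cooccurrence"],
            )
        except (KeyError, TypeError) as exc:
            raise RegistryError(f"registry config {path} missing key: {exc}") from exc
        for p in (*cfg.spec_paths, cfg.hierarchy_path, cfg.normalizer_path, cfg.cooccurrence_path):
            if not Path(p).exists():
                raise RegistryError(f"configured path does not exist: {p}")
        return cfg


@dataclass(frozen=True)
class MetaEdge:
    """Meta-KG edge: a category pair linked by one operation's predicate."""

    subject_category: str
    predicate: str
    object_category: str
    op_ref: str


@dataclass
class MetaKG:
    """Graph over semantic categories; edges are annotated API operations."""

    categories: set[str] = field(default_factory=set)
    edges: list[MetaEdge] = field(default_factory=list)
    operations: dict[str, OperationAnnotation] = field(default_factory=dict)
    by_pair: dict[tuple[str, str], list[MetaEdge]] = field(default_factory=dict)

    def op(self, op_id: str) -> OperationAnnotation:
        return self.operations[op_id]


def _require_str(block: dict, key: str, where: str) -> str:
    value = block.get(key)
    if not isinstance(value, str) or not value:
        raise SpecValidationError(f"{where}: missing or empty required field {key!r}")
    return value


def _parse_operation(block: dict, api_name: str, server_url: str, path: str,
                     hierarchy: CategoryHierarchy) -> OperationAnnotation:
    if not isinstance(block, dict):
        raise SpecValidationError(f"{api_name} {path}: x-kg-operations entries must be objects")
    where = f"{api_name} {path} op {block.get('op_id', '<missing op_id>')!r}"
    fields = {key: _require_str(block, key, where) for key in _REQUIRED_OP_FIELDS}

    method = str(block.get("method", "GET")).upper()
    if method not in _METHODS:
        raise SpecValidationError(f"{where}: method must be GET or POST, got {method!r}")

    for key in ("input_category", "output_category"):
        if fields[key] not in hierarchy.categories:
            raise SpecValidationError(f"{where}: unknown category {fields[key]!r}")
    if fields["predicate"] not in hierarchy.predicates:
        raise SpecValidationError(f"{where}: unknown predicate {fields['predicate']!r}")

    template = fields["request_template"]
    if template.count("{inputs}") != 1:
        raise SpecValidationError(
            f"{where}: request_template must contain '{{inputs}}' exactly once"
        )

    id_path = parse_id_path(fields["response_id_path"])

    max_batch = block.get("max_batch", DEFAULT_MAX_BATCH)
    if not isinstance(max_batch, int) or isinstance(max_batch, bool) or max_batch < 1:
        raise SpecValidationError(f"{where}: max_batch must be a positive integer")

    return OperationAnnotation(
        op_id=fields["op_id"],
        api_name=api_name,
        server_url=server_url,
        path=path,
        method=method,
        input_category=fields["input_category"],
        input_prefix=fields["input_prefix"],
        output_category=fields["output_category"],
        output_prefix=fields["output_prefix"],
        predicate=fields["predicate"],
        request_template=template,
        response_id_path=id_path,
        max_batch=max_batch,
    )


def parse_api_spec(text: str, hierarchy: CategoryHierarchy) -> APISpec:
    """Parse and validate one annotated API spec document (JSON or YAML).

    Unknown OpenAPI keys are tolerated and ignored; only ``info``,
    ``servers`` and the per-path ``x-kg-operations`` blocks are interpreted.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SpecValidationError(f"unparseable spec document: {exc}") from exc
    if not isinstance(doc, dict):
        raise SpecValidationError("spec document must be a mapping at top level")

    info = doc.get("info") or {}
    title = str(info.get("title", ""))
    if not title:
        raise SpecValidationError("spec missing info.title")
    version = str(info.get("version", "0.0"))
    servers = doc.get("servers") or []
    server_url = str(servers[0].get("url", "")) if servers else ""

    operations: list[OperationAnnotation] = []
    seen: set[str] = set()
    for path, path_item in sorted((doc.get("paths") or {}).items()):
        if not isinstance(path_item, dict):
            continue
        for block in path_item.get("x-kg-operations") or []:
            op = _parse_operation(block, title, server_url, path, hierarchy)
            if op.op_id in seen:
                raise SpecValidationError(f"{title}: duplicate op_id {op.op_id!r} within spec")
            seen.add(op.op_id)
            operations.append(op)

    return APISpec(
        api_name=title,
        title=title,
        version=version,
        server_url=server_url,
        operations=tuple(operations),
    )


def load_api_spec(path: str | Path, hierarchy: CategoryHierarchy) -> APISpec:
    return parse_api_spec(Path(path).read_text(encoding="utf-8"), hierarchy)


def serialize_api_spec(spec: APISpec) -> str:
    """Render an APISpec back to its JSON document form (deterministic).

    ``parse_api_spec(serialize_api_spec(s))`` yields a spec equal to ``s``.
    """
    paths: dict[str, dict] = {}
    for op in spec.operations:
        block = {
            "op_id": op.op_id,
            "method": op.method,
            "input_category": op.input_category,
            "input_prefix": op.input_prefix,
            "predicate": op.predicate,
            "output_category": op.output_category,
            "output_prefix": op.output_prefix,
            "request_template": op.request_template,
            "response_id_path": str(op.response_id_path),
            "max_batch": op.max_batch,
        }
        paths.setdefault(op.path, {"x-kg-operations": []})["x-kg-operations"].append(block)
    doc = {
        "info": {"title": spec.title, "version": spec.version},
        "servers": [{"url": spec.server_url}],
        "paths": paths,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def build_meta_kg(specs: list[APISpec]) -> MetaKG:
    """Assemble the meta-KG; one MetaEdge per operation across all specs."""
    kg = MetaKG()
    for spec in specs:
        for op in spec.operations:
            if op.op_id in kg.operations:
                raise RegistryError(f"duplicate op_id {op.op_id!r} across specs")
            kg.operations[op.op_id] = op
            edge = MetaEdge(
                subject_category=op.input_category,
                predicate=op.predicate,
                object_category=op.output_category,
                op_ref=op.op_id,
            )
            kg.edges.append(edge)
            kg.categories.update((op.input_category, op.output_category))
            kg.by_pair.setdefault((op.input_category, op.output_category), []).append(edge)
    return kg


def meta_kg_summary(kg: MetaKG) -> list[dict]:
    """Per ordered category pair: distinct API count and operation count.

    Rows are sorted by (subject, object); operation counts over all rows sum
    to the number of meta-edges.
    """
    rows = []
    for (subject, obj), edges in sorted(kg.by_pair.items()):
        apis = {kg.operations[e.op_ref].api_name for e in edges}
        rows.append(
            {
                "subject_category": subject,
                "object_category": obj,
                "n_apis": len(apis),
                "n_operations": len(edges),
            }
        )
    return rows


def load_registry(config: RegistryConfig) -> tuple[CategoryHierarchy, list[APISpec], MetaKG]:
    """Load hierarchy and all configured specs, and build the meta-KG."""
    hierarchy = load_hierarchy(config.hierarchy_path)
    specs = [load_api_spec(p, hierarchy) for p in config.spec_paths]
    return hierarchy, specs, build_meta_kg(specs)
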