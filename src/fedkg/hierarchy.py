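"""Miniature category/predicate hierarchy (a Biolink-style vocabulary).

The engine matches API operations against query constraints through two small
single-inheritance trees: one over semantic categories (``Disease``, ``Gene``,
``ChemicalEntity``, ...) and one over predicates (``related_to``,
``treats``, ...). The file format is deliberately tiny:

* UTF-8 text, one ``child<TAB>parent`` pair per line;
* a line ``name<TAB>-`` marks ``name`` as a root;
* a line consisting of ``#predicates`` separates the category block (first)
  from the predicate block (second);
* blank lines and lines starting with ``#`` (other than the separator) are
  ignored.

Both trees must be acyclic and every non-root must have exactly one parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import HierarchyError

__all__ = ["Tree", "CategoryHierarchy", "load_hierarchy", "parse_hierarchy", "expand"]


@dataclass
class Tree:
    """One single-inheritance tree: token -> parent (roots map to None)."""

    parents: dict[str, str | None] = field(default_factory=dict)
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rebuild_children()
        self._check_acyclic()

    def _rebuild_children(self) -> None:
        self._children = {name: [] for name in self.parents}
        for child, parent in self.parents.items():
            if parent is not None:
                if parent not in self.parents:
                    raise HierarchyError(f"unknown parent {parent!r} of {child!r}")
                self._children[parent].append(child)
        for kids in self._children.values():
            kids.sort()

    def _check_acyclic(self) -> None:
        for start in self.parents:
            seen = {start}
            node = self.parents[start]
            while node is not None:
                if node in seen:
                    raise HierarchyError(f"cycle detected at {node!r}")
                seen.add(node)
                node = self.parents[node]

    def __contains__(self, name: str) -> bool:
        return name in self.parents

    def require(self, name: str) -> None:
        if name not in self.parents:
            raise HierarchyError(f"unknown token {name!r}")

    def descendants(self, name: str) -> set[str]:
        """All tokens at or below ``name`` (reflexive)."""
        self.require(name)
        out: set[str] = set()
        stack = [name]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(self._children[node])
        return out

    def is_a(self, name: str, ancestor: str) -> bool:
        """True when ``name`` equals ``ancestor`` or descends from it."""
        self.require(name)
        self.require(ancestor)
        node: str | None = name
        while node is not None:
            if node == ancestor:
                return True
            node = self.parents[node]
        return False


@dataclass
class CategoryHierarchy:
    """Paired category and predicate trees loaded from one hierarchy file."""

    categories: Tree
    predicates: Tree

    def descendants(self, category: str) -> set[str]:
        return self.categories.descendants(category)

    def predicate_descendants(self, predicate: str) -> set[str]:
        return self.predicates.descendants(predicate)


def _parse_block(lines: list[tuple[int, str]]) -> Tree:
    parents: dict[str, str | None] = {}
    for lineno, line in lines:
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise HierarchyError(f"line {lineno}: expected 'child<TAB>parent', got {line!r}")
        child, parent = parts
        if child in parents:
            raise HierarchyError(f"line {lineno}: duplicate entry for {child!r}")
        parents[child] = None if parent == "-" else parent
    if parents and not any(p is None for p in parents.values()):
        raise HierarchyError("block has no root (no 'name<TAB>-' line)")
    return Tree(parents)


def parse_hierarchy(text: str) -> CategoryHierarchy:
    """Parse hierarchy file content; see module docstring for the format."""
    blocks: list[list[tuple[int, str]]] = [[], []]
    current = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.strip() == "#predicates":
            if current == 1:
                raise HierarchyError(f"line {lineno}: duplicate '#predicates' separator")
            current = 1
            continue
        if line.lstrip().startswith("#"):
            continue
        blocks[current].append((lineno, line))
    return CategoryHierarchy(categories=_parse_block(blocks[0]), predicates=_parse_block(blocks[1]))


def load_hierarchy(path: str | Path) -> CategoryHierarchy:
    """Load and validate a hierarchy file from disk."""
    return parse_hierarchy(Path(path).read_text(encoding="utf-8"))


def expand(token: str, tree: Tree) -> set[str]:
    """The token plus all of its descendants (reflexive closure downwards).

    Monotone along the tree: if A is an ancestor of B then
    ``expand(B) <= expand(A)``.
    """
    return tree.descendants(token)
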