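"""The two-level Hallmarks-of-Cancer taxonomy.

The taxonomy is a forest of 37 nodes: ten top-level hallmarks (e.g.
"Resisting cell death", "Inducing angiogenesis") and 27 nested cellular or
molecular processes (e.g. "Apoptosis" under "Resisting cell death").  Nodes
are keyed by dotted codes ("3", "3.1", "7.1.2"); a node's parent is its code
with the final component removed.  Training, prediction post-processing and
reporting all consult this structure through :meth:`Taxonomy.ancestors`.

Variant taxonomies can be loaded from a three-column TSV (``code``, ``name``,
``parent``), so the machinery is reusable beyond the shipped hierarchy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterator, List, Optional

__all__ = [
    "TaxonomyNode",
    "Taxonomy",
    "load_default_taxonomy",
    "UnknownCodeError",
]


class UnknownCodeError(KeyError):
    """Raised when a node code is not present in the taxonomy."""


@dataclass(frozen=True)
class TaxonomyNode:
    """One node of the hallmark hierarchy.

    ``level`` equals the number of dot-separated components of ``code``;
    ``parent_code`` is ``code`` minus its last component, or ``None`` for a
    top-level hallmark.
    """

    code: str
    name: str
    parent_code: Optional[str]
    level: int

    @staticmethod
    def from_code(code: str, name: str) -> "TaxonomyNode":
        parts = code.split(".")
        parent = ".".join(parts[:-1]) if len(parts) > 1 else None
        return TaxonomyNode(code=code, name=name, parent_code=parent, level=len(parts))


class Taxonomy:
    """A forest of :class:`TaxonomyNode` keyed by code."""

    def __init__(self, nodes: List[TaxonomyNode]):
        self.nodes: Dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.code in self.nodes:
                raise ValueError(f"duplicate taxonomy code {node.code!r}")
            self.nodes[node.code] = node

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, code: str) -> bool:
        return code in self.nodes

    def __iter__(self) -> Iterator[TaxonomyNode]:
        return iter(self.nodes.values())

    @property
    def codes(self) -> List[str]:
        return list(self.nodes.keys())

    def roots(self) -> List[TaxonomyNode]:
        return [n for n in self.nodes.values() if n.parent_code is None]

    def children(self, code: str) -> List[TaxonomyNode]:
        self._require(code)
        return [n for n in self.nodes.values() if n.parent_code == code]

    def node(self, code: str) -> TaxonomyNode:
        self._require(code)
        return self.nodes[code]

    def ancestors(self, code: str) -> List[str]:
        """Chain of ancestor codes from immediate parent up to the root.

        Roots return an empty list.  Unknown codes raise
        :class:`UnknownCodeError`.
        """
        self._require(code)
        chain: List[str] = []
        current = self.nodes[code].parent_code
        while current is not None:
            chain.append(current)
            current = self.nodes[current].parent_code if current in self.nodes else None
        return chain

    def name_to_code(self) -> Dict[str, str]:
        """Map from node name to code, restricted to unambiguous names."""
        counts: Dict[str, int] = {}
        for n in self.nodes.values():
            counts[n.name] = counts.get(n.name, 0) + 1
        return {n.name: n.code for n in self.nodes.values() if counts[n.name] == 1}

    def validate(self) -> List[str]:
        """Return violation descriptions; empty iff the structure is sound.

        Checks: level/code agreement, parent derivability, orphaned parents,
        and cycle-freeness (the dotted-code construction already rules out
        cycles, but a hand-built node list may not honour it).
        """
        violations: List[str] = []
        for node in self.nodes.values():
            parts = node.code.split(".")
            if node.level != len(parts):
                violations.append(
                    f"{node.code}: level {node.level} != component count {len(parts)}"
                )
            expected_parent = ".".join(parts[:-1]) if len(parts) > 1 else None
            if node.parent_code != expected_parent:
                violations.append(
                    f"{node.code}: parent_code {node.parent_code!r} is not the "
                    f"code prefix {expected_parent!r}"
                )
            if node.parent_code is not None and node.parent_code not in self.nodes:
                violations.append(
                    f"{node.code}: orphan, parent {node.parent_code!r} missing"
                )
        # Cycle check by walking parents with a step bound.
        for node in self.nodes.values():
            seen = {node.code}
            current = node.parent_code
            while current is not None and current in self.nodes:
                if current in seen:
                    violations.append(f"{node.code}: cycle through {current!r}")
                    break
                seen.add(current)
                current = self.nodes[current].parent_code
        return violations

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        """Load a taxonomy from ``code\\tname\\tparent`` TSV (UTF-8)."""
        nodes: List[TaxonomyNode] = []
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if [h.strip() for h in header[:2]] != ["code", "name"]:
                raise ValueError(f"unexpected taxonomy header {header!r} in {path}")
            for row in reader:
                if not row or not row[0].strip():
                    continue
                code = row[0].strip()
                name = row[1].strip()
                nodes.append(TaxonomyNode.from_code(code, name))
        return cls(nodes)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("code\tname\tparent\n")
            for node in self.nodes.values():
                parent = node.parent_code or ""
                fh.write(f"{node.code}\t{node.name}\t{parent}\n")

    # ------------------------------------------------------------- internal

    def _require(self, code: str) -> None:
        if code not in self.nodes:
            raise UnknownCodeError(code)


def load_default_taxonomy() -> Taxonomy:
    """The built-in 37-node hallmark taxonomy (10 hallmarks, 27 subclasses).

    The subclass "By evading contact inhibition" is stored under code ``2.2``
    so that codes are unique keys; its printed name is preserved.
    """
    ref = resources.files("hocmine.data").joinpath("hallmark_taxonomy.tsv")
    with resources.as_file(ref) as path:
        taxonomy = Taxonomy.from_tsv(path)
    return taxonomy
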