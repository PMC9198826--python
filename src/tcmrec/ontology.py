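"""Drug classification hierarchy and first-category rollup.

Herb drugs are organised in a three-level hierarchy: leaf drugs (the
ingredients a physician actually orders), category-II formula groups, and
first-category (top-level) therapeutic classes.  Two different herbs under
the same first category are treated as clinically interchangeable, so
evaluation compares prescriptions after *rolling up* every drug to its
first-category ancestor.  Western medicines without a class hierarchy are
modelled as leaves that are their own first category.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["DrugNode", "DrugOntology", "OntologyError", "load_ontology"]

LEVELS = ("leaf", "category2", "category1")


class OntologyError(ValueError):
    """Structural problem in an ontology table (dangling parent, cycle...)."""


@dataclass(frozen=True)
class DrugNode:
    id: str
    name: str
    level: str  # "leaf" | "category2" | "category1"
    parent_id: str | None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise OntologyError(f"unknown level {self.level!r} for node {self.id!r}")
        if self.level == "category1" and self.parent_id is not None:
            raise OntologyError(f"category1 node {self.id!r} must not have a parent")


class DrugOntology:
    """Validated id->node map with memoised first-category lookup."""

    def __init__(self, nodes: Iterable[DrugNode]):
        self.nodes: dict[str, DrugNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise OntologyError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        self._validate()
        self._cat1_cache: dict[str, str] = {}

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise OntologyError(
                    f"node {node.id!r} references missing parent {node.parent_id!r}"
                )
        # walk every chain; bounded by node count so any cycle is caught
        limit = len(self.nodes)
        for node in self.nodes.values():
            cur, steps = node, 0
            while cur.parent_id is not None:
                cur = self.nodes[cur.parent_id]
                steps += 1
                if steps > limit:
                    raise OntologyError(f"cycle detected through node {node.id!r}")
            if cur.level != "category1" and node.level != "category1":
                # roots other than category1 are allowed only for parentless
                # leaves (Western medicines: singleton categories)
                if cur is not node or cur.level != "leaf":
                    raise OntologyError(
                        f"ancestor chain of {node.id!r} ends at non-category1 "
                        f"root {cur.id!r}"
                    )

    @property
    def n_category1(self) -> int:
        return sum(1 for n in self.nodes.values() if n.level == "category1")

    def category1_ids(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.level == "category1")

    def first_category(self, drug_id: str) -> str:
        """First-category ancestor; identity for category1 nodes and for
        parentless leaves (Western medicines form singleton categories)."""
        if drug_id in self._cat1_cache:
            return self._cat1_cache[drug_id]
        if drug_id not in self.nodes:
            raise KeyError(f"unknown drug id {drug_id!r}")
        cur = self.nodes[drug_id]
        path = []
        while cur.parent_id is not None and cur.id not in self._cat1_cache:
            path.append(cur.id)
            cur = self.nodes[cur.parent_id]
        root = self._cat1_cache.get(cur.id, cur.id)
        for node_id in path + [self.nodes[drug_id].id]:
            self._cat1_cache[node_id] = root
        return root

    def category2(self, drug_id: str) -> str:
        """Category-II ancestor (identity above leaf level); the alternative
        rollup granularity for formula-level rather than class-level scoring."""
        if drug_id not in self.nodes:
            raise KeyError(f"unknown drug id {drug_id!r}")
        cur = self.nodes[drug_id]
        while cur.level == "leaf" and cur.parent_id is not None:
            cur = self.nodes[cur.parent_id]
        return cur.id

    def rollup(self, prescription: Iterable[str], level: str = "category1") -> set[str]:
        """Map a set of drug ids to the set of their ancestors at `level`."""
        if level == "category1":
            return {self.first_category(d) for d in prescription}
        if level == "category2":
            return {self.category2(d) for d in prescription}
        raise ValueError(f"unknown rollup level {level!r}")

    def leaves(self) -> list[DrugNode]:
        return [n for n in self.nodes.values() if n.level == "leaf"]

    def leaves_of_category(self, cat1_id: str) -> list[str]:
        return sorted(
            n.id for n in self.leaves() if self.first_category(n.id) == cat1_id
        )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "name", "level", "parent_id"])
            for node_id in sorted(self.nodes):
                n = self.nodes[node_id]
                writer.writerow([n.id, n.name, n.level, n.parent_id or ""])


def load_ontology(path: str | Path) -> DrugOntology:
    """Read an ontology from CSV with header ``id,name,level,parent_id``."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "name", "level", "parent_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise OntologyError(
                f"ontology CSV must have header id,name,level,parent_id; "
                f"got {reader.fieldnames}"
            )
        nodes = [
            DrugNode(
                id=row["id"],
                name=row["name"],
                level=row["level"],
                parent_id=row["parent_id"] or None,
            )
            for row in reader
        ]
    return DrugOntology(nodes)
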