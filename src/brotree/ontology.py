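"""Hierarchical region ontology: a rooted tree of brain regions.

The ontology is the backbone of the agreement analysis: every sample is
annotated to a region, and the distance between two samples is the number
of edges on the unique path between their regions.  Regions may sit at any
depth — samples annotated to internal nodes are treated uniformly.  All
edges have weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "RegionOntology",
    "OntologyError",
    "parse_ontology",
    "build_ontology",
    "prune_to_regions",
    "write_ontology",
]


class OntologyError(ValueError):
    """Structural problem in an ontology table (duplicates, cycles, bad parents)."""


@dataclass(frozen=True)
class Region:
    """One node of the region tree; ``parent_id is None`` marks the root."""

    region_id: str
    parent_id: Optional[str]
    name: str = ""
    acronym: str = ""


class RegionOntology:
    """A validated rooted tree of :class:`Region` nodes.

    Tree distances (edge counts) are computed through the lowest common
    ancestor and cached as a full region x region matrix on first use; the
    trees here have at most a few thousand nodes so the cache is small.
    """

    def __init__(self, regions: Sequence[Region]):
        self.regions: dict[str, Region] = {}
        for r in regions:
            if r.region_id in self.regions:
                raise OntologyError(f"duplicate region id: {r.region_id!r}")
            self.regions[r.region_id] = r
        roots = [r.region_id for r in regions if r.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {len(roots)}: {roots}")
        self.root: str = roots[0]
        self.children: dict[str, list[str]] = {rid: [] for rid in self.regions}
        for r in regions:
            if r.parent_id is None:
                continue
            if r.parent_id not in self.regions:
                raise OntologyError(
                    f"missing parent: region {r.region_id!r} references "
                    f"nonexistent parent {r.parent_id!r}"
                )
            self.children[r.parent_id].append(r.region_id)
        for rid in self.children:
            self.children[rid].sort()
        self._validate_tree()
        self._index: dict[str, int] = {rid: i for i, rid in enumerate(sorted(self.regions))}
        self._ids: list[str] = sorted(self.regions)
        self._depth: dict[str, int] = self._compute_depths()
        self._dist: Optional[np.ndarray] = None

    def _validate_tree(self) -> None:
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise OntologyError(f"cycle detected at region {node!r}")
            seen.add(node)
            stack.extend(self.children[node])
        unreachable = set(self.regions) - seen
        if unreachable:
            raise OntologyError(
                f"regions not reachable from root (cycle or orphan subtree): "
                f"{sorted(unreachable)}"
            )

    def _compute_depths(self) -> dict[str, int]:
        depth = {self.root: 0}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in self.children[node]:
                depth[c] = depth[node] + 1
                stack.append(c)
        return depth

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.regions

    @property
    def region_ids(self) -> list[str]:
        return list(self._ids)

    def depth(self, region_id: str) -> int:
        return self._depth[region_id]

    def ancestors(self, region_id: str) -> list[str]:
        """Path from ``region_id`` up to (and including) the root."""
        self._check(region_id)
        path = [region_id]
        while self.regions[path[-1]].parent_id is not None:
            path.append(self.regions[path[-1]].parent_id)  # type: ignore[arg-type]
        return path

    def descendants(self, region_id: str) -> set[str]:
        """All regions in the subtree rooted at ``region_id`` (inclusive)."""
        self._check(region_id)
        out: set[str] = set()
        stack = [region_id]
        while stack:
            node = stack.pop()
            out.add(node)
            stack.extend(self.children[node])
        return out

    def _check(self, region_id: str) -> None:
        if region_id not in self.regions:
            raise KeyError(f"unknown region id: {region_id!r}")

    def tree_distance(self, a: str, b: str) -> int:
        """Number of edges on the unique path between regions ``a`` and ``b``."""
        self._check(a)
        self._check(b)
        if a == b:
            return 0
        da, db = self._depth[a], self._depth[b]
        ua, ub = a, b
        while da > db:
            ua = self.regions[ua].parent_id  # type: ignore[assignment]
            da -= 1
        while db > da:
            ub = self.regions[ub].parent_id  # type: ignore[assignment]
            db -= 1
        while ua != ub:
            ua = self.regions[ua].parent_id  # type: ignore[assignment]
            ub = self.regions[ub].parent_id  # type: ignore[assignment]
            da -= 1
        return self._depth[a] + self._depth[b] - 2 * da

    def distance_matrix(self) -> np.ndarray:
        """Full pairwise edge-count matrix, rows/cols in ``region_ids`` order."""
        if self._dist is None:
            n = len(self._ids)
            d = np.zeros((n, n), dtype=np.int64)
            for i, a in enumerate(self._ids):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = self.tree_distance(a, self._ids[j])
            self._dist = d
        return self._dist

    def region_index(self, region_ids: Iterable[str]) -> np.ndarray:
        """Integer positions of ``region_ids`` in the distance-matrix ordering."""
        return np.array([self._index[r] for r in region_ids], dtype=np.int64)

    def to_newick(self) -> str:
        """Newick export (node labels are region ids) for inspection / oracles."""

        def rec(node: str) -> str:
            kids = self.children[node]
            if not kids:
                return node
            return "(" + ",".join(rec(c) for c in kids) + ")" + node

        return rec(self.root) + ";"


def build_ontology(regions: Sequence[Region]) -> RegionOntology:
    """Validate a collection of regions into a :class:`RegionOntology`."""
    return RegionOntology(regions)


def parse_ontology(path) -> RegionOntology:
    """Read an ontology table (``region_id  parent_id  name  acronym``, tab
    separated, empty ``parent_id`` marks the root) and validate it."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    required = {"region_id", "parent_id"}
    missing = required - set(df.columns)
    if missing:
        raise OntologyError(f"ontology table missing columns: {sorted(missing)}")
    regions = []
    for row in df.itertuples(index=False):
        parent = row.parent_id if row.parent_id != "" else None
        regions.append(
            Region(
                region_id=row.region_id,
                parent_id=parent,
                name=getattr(row, "name", "") or "",
                acronym=getattr(row, "acronym", "") or "",
            )
        )
    return RegionOntology(regions)


def write_ontology(ont: RegionOntology, path) -> None:
    """Write the ontology in the same table dialect :func:`parse_ontology` reads."""
    rows = [
        {
            "region_id": r.region_id,
            "parent_id": r.parent_id if r.parent_id is not None else "",
            "name": r.name,
            "acronym": r.acronym,
        }
        for r in (ont.regions[rid] for rid in ont.region_ids)
    ]
    pd.DataFrame(rows, columns=["region_id", "parent_id", "name", "acronym"]).to_csv(
        path, sep="\t", index=False
    )


def prune_to_regions(ont: RegionOntology, keep: Iterable[str]) -> RegionOntology:
    """Restrict the ontology to ``keep``: each kept node is re-parented to its
    nearest kept proper ancestor and distances are those of the pruned tree.

    The kept set must induce a single root (one kept node with no kept
    ancestor), otherwise an :class:`OntologyError` is raised.
    """
    keep_set = set(keep)
    unknown = keep_set - set(ont.regions)
    if unknown:
        raise OntologyError(f"unknown regions in keep set: {sorted(unknown)}")
    new_regions = []
    roots = []
    for rid in sorted(keep_set):
        parent = ont.regions[rid].parent_id
        while parent is not None and parent not in keep_set:
            parent = ont.regions[parent].parent_id
        if parent is None:
            roots.append(rid)
        old = ont.regions[rid]
        new_regions.append(Region(rid, parent, old.name, old.acronym))
    if len(roots) != 1:
        raise OntologyError(
            f"pruned region set induces {len(roots)} roots: {roots}"
        )
    return RegionOntology(new_regions)
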