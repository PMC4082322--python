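"""Distance matrices, unrooted tree graphs, newick and PHYLIP I/O.

Trees are exposed to callers as :class:`dendropy.Tree` objects (newick
round-trips, reroots and pretty printing come for free); the tree-search
code in the phylogeny modules works on a small mutable unrooted graph
(:class:`TreeGraph`) and converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

log = logging.getLogger(__name__)

#: Public tree type used across the package.
PhyloTree = dendropy.Tree


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} != ({n}, {n})")
        if not np.allclose(vals, vals.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")
        if (vals < -1e-12).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def reordered(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


def write_phylip(dm: DistanceMatrix, path: str | Path, strict: bool = False) -> None:
    """PHYLIP square matrix; classic 10-character labels when *strict*."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for label, row in zip(dm.labels, dm.values):
            if strict:
                name = label[:10].ljust(10)
            else:
                name = label + "  "
            fh.write(name + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path: str | Path, strict: bool = False) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (strict or relaxed dialect)."""
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            line = fh.readline()
            if strict:
                labels.append(line[:10].strip())
                rows.append([float(x) for x in line[10:].split()])
            else:
                parts = line.split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(tuple(labels), np.array(rows))


# ---------------------------------------------------------------------------
# Unrooted tree graph used by the NJ / Fitch–Margoliash builders
# ---------------------------------------------------------------------------

class TreeGraph:
    """A small mutable unrooted tree: integer nodes, labeled leaves."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.leaf_label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.leaf_label[nid] = label
        return nid

    def add_edge(self, a: int, b: int, length: float = 0.0) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def remove_edge(self, a: int, b: int) -> None:
        del self.adj[a][b]
        del self.adj[b][a]

    def set_length(self, a: int, b: int, length: float) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    # -- queries ------------------------------------------------------------
    def edges(self) -> list[tuple[int, int]]:
        seen = []
        for a in sorted(self.adj):
            for b in sorted(self.adj[a]):
                if a < b:
                    seen.append((a, b))
        return seen

    def leaves(self) -> list[int]:
        return sorted(self.leaf_label)

    def copy(self) -> "TreeGraph":
        t = TreeGraph()
        t.adj = {a: dict(nb) for a, nb in self.adj.items()}
        t.leaf_label = dict(self.leaf_label)
        t._next = self._next
        return t

    def split_for_edge(self, a: int, b: int) -> frozenset[str]:
        """Leaf labels on the *a*-side of edge (a, b)."""
        side: set[str] = set()
        stack = [a]
        seen = {b}
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in self.leaf_label:
                side.add(self.leaf_label[node])
            stack.extend(self.adj[node])
        return frozenset(side)

    def path_length_matrix(self, labels: Sequence[str]) -> np.ndarray:
        """Pairwise leaf path lengths in the order of *labels*."""
        by_label = {l: n for n, l in self.leaf_label.items()}
        n = len(labels)
        out = np.zeros((n, n))
        for i, la in enumerate(labels):
            dist = {by_label[la]: 0.0}
            stack = [by_label[la]]
            while stack:
                node = stack.pop()
                for nb, ln in self.adj[node].items():
                    if nb not in dist:
                        dist[nb] = dist[node] + ln
                        stack.append(nb)
            for j, lb in enumerate(labels):
                out[i, j] = dist[by_label[lb]]
        return out

    def edge_pair_incidence(self, labels: Sequence[str]) -> np.ndarray:
        """0/1 matrix: rows = unordered label pairs (i<j), cols = edges."""
        edges = self.edges()
        pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
        A = np.zeros((len(pairs), len(edges)))
        universe = frozenset(labels)
        for e_idx, (a, b) in enumerate(edges):
            side = self.split_for_edge(a, b)
            for p_idx, (i, j) in enumerate(pairs):
                if (labels[i] in side) != (labels[j] in side):
                    A[p_idx, e_idx] = 1.0
        assert universe  # labels non-empty
        return A

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (a, b)
            for a, b in self.edges()
            if a not in self.leaf_label and b not in self.leaf_label
        ]

    # -- newick -------------------------------------------------------------
    def to_newick(self) -> str:
        root = next(
            (n for n in sorted(self.adj) if n not in self.leaf_label), None
        )
        if root is None:  # two-leaf degenerate tree
            (a, b) = sorted(self.adj)
            return f"({self.leaf_label[a]}:{self.adj[a][b] / 2:.10g},{self.leaf_label[b]}:{self.adj[a][b] / 2:.10g});"

        def rec(node: int, parent: int | None) -> str:
            children = [nb for nb in sorted(self.adj[node]) if nb != parent]
            if not children:
                return self.leaf_label[node]
            inner = ",".join(
                f"{rec(c, node)}:{self.adj[node][c]:.10g}" for c in children
            )
            return f"({inner})"

        return rec(root, None) + ";"

    def to_dendropy(self) -> PhyloTree:
        return tree_from_newick(self.to_newick())


# ---------------------------------------------------------------------------
# dendropy helpers
# ---------------------------------------------------------------------------

def tree_from_newick(newick: str | Path) -> PhyloTree:
    if isinstance(newick, Path):
        newick = newick.read_text()
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def tree_to_newick(tree: PhyloTree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def leaf_labels(tree: PhyloTree) -> list[str]:
    return sorted(l.taxon.label for l in tree.leaf_node_iter())


def bipartitions(tree: PhyloTree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial splits of an (un)rooted tree as {side, complement} pairs."""
    universe = frozenset(leaf_labels(tree))
    splits: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = universe - side
        if 2 <= len(side) <= len(universe) - 2:
            splits.add(frozenset({side, other}))
    return splits


def clamp_negative_branches(tree_or_graph, context: str = "") -> int:
    """Clamp negative branch lengths to zero; returns the number clamped."""
    n = 0
    if isinstance(tree_or_graph, TreeGraph):
        for a, b in tree_or_graph.edges():
            if tree_or_graph.adj[a][b] < 0:
                tree_or_graph.set_length(a, b, 0.0)
                n += 1
    else:
        for edge in tree_or_graph.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                edge.length = 0.0
                n += 1
    if n:
        log.info("clamped %d negative branch length(s) %s", n, context)
    return n
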