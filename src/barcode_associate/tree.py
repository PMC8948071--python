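"""Unrooted phylogenetic trees over specimen IDs.

A small adjacency-based tree structure tailored to what the pipeline needs:
branch lengths, bipartition (split) extraction for monophyly tests and
bootstrap support, nearest-neighbor-interchange rearrangements, path
distances, and Newick round-tripping with support values as internal node
labels. Splits are represented canonically as the frozenset of leaf names on
the side *not* containing the lexicographically first taxon, so equality of
splits is equality of clades on an unrooted tree.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


class TreeError(ValueError):
    pass


class PhyloTree:
    """Unrooted tree: leaves carry specimen IDs, edges carry lengths.

    ``support`` maps canonical splits (see module docstring) to bootstrap
    percentages in [0, 100].
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.leaf_name: dict[int, str] = {}
        self.support: dict[frozenset[str], float] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def add_node(self, name: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        if name is not None:
            self.leaf_name[nid] = name
        return nid

    def add_edge(self, a: int, b: int, length: float) -> None:
        if length < 0:
            raise TreeError(f"negative branch length {length}")
        self.adj[a][b] = length
        self.adj[b][a] = length

    def remove_edge(self, a: int, b: int) -> None:
        del self.adj[a][b]
        del self.adj[b][a]

    def remove_node(self, nid: int) -> None:
        for nb in list(self.adj[nid]):
            self.remove_edge(nid, nb)
        del self.adj[nid]
        self.leaf_name.pop(nid, None)

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {v: dict(nbrs) for v, nbrs in self.adj.items()}
        t.leaf_name = dict(self.leaf_name)
        t.support = dict(self.support)
        t._next_id = self._next_id
        return t

    # -- basic queries -------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_name.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_name)

    def node_of(self, name: str) -> int:
        for nid, nm in self.leaf_name.items():
            if nm == name:
                return nid
        raise KeyError(name)

    def is_leaf(self, nid: int) -> bool:
        return nid in self.leaf_name

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for a, nbrs in self.adj.items():
            for b, ln in nbrs.items():
                if a < b:
                    out.append((a, b, ln))
        return out

    def branch_length(self, a: int, b: int) -> float:
        return self.adj[a][b]

    def set_branch_length(self, a: int, b: int, length: float) -> None:
        self.adj[a][b] = length
        self.adj[b][a] = length

    def traverse_postorder(self, root: int) -> Iterator[tuple[int, int | None]]:
        """Yield (node, parent) in postorder from ``root``."""
        stack = [(root, None, False)]
        while stack:
            node, parent, expanded = stack.pop()
            if expanded:
                yield node, parent
                continue
            stack.append((node, parent, True))
            for nb in sorted(self.adj[node]):
                if nb != parent:
                    stack.append((nb, node, False))

    # -- splits --------------------------------------------------------

    def _leafsets(self) -> dict[tuple[int, int], frozenset[str]]:
        """For each directed edge (parent, child): leaf names under child."""
        ref = self.node_of(min(self.taxa))
        below: dict[int, set[str]] = {}
        sides: dict[tuple[int, int], frozenset[str]] = {}
        for node, parent in self.traverse_postorder(ref):
            names = {self.leaf_name[node]} if self.is_leaf(node) else set()
            for nb in self.adj[node]:
                if nb != parent:
                    names |= below[nb]
            below[node] = names
            if parent is not None:
                sides[(parent, node)] = frozenset(names)
        return sides

    def splits(self) -> dict[frozenset[str], tuple[int, int]]:
        """Canonical split -> (parent, child) edge, child side excludes ref taxon."""
        return {side: edge for edge, side in self._leafsets().items()}

    def nontrivial_splits(self) -> set[frozenset[str]]:
        """Splits with >= 2 leaves on both sides (internal edges)."""
        n = self.n_leaves
        return {s for s in self.splits() if 2 <= len(s) <= n - 2}

    def canonical_split(self, names: set[str] | frozenset[str]) -> frozenset[str]:
        """Normalize an arbitrary leaf subset to the canonical split key."""
        taxa = set(self.taxa)
        if not names or not names <= taxa:
            raise TreeError("subset must be a non-empty subset of the leaf set")
        ref = min(taxa)
        return frozenset(taxa - names) if ref in names else frozenset(names)

    def has_split(self, names: set[str] | frozenset[str]) -> bool:
        key = self.canonical_split(names)
        if len(key) in (0, 1, self.n_leaves - 1, self.n_leaves):
            return True  # trivial splits exist in every unrooted tree
        return key in self.splits()

    def support_for(self, names: set[str] | frozenset[str]) -> float | None:
        return self.support.get(self.canonical_split(names))

    # -- metrics -------------------------------------------------------

    def path_distance(self, name_a: str, name_b: str) -> float:
        a, b = self.node_of(name_a), self.node_of(name_b)
        dist = {a: 0.0}
        stack = [a]
        while stack:
            v = stack.pop()
            if v == b:
                return dist[v]
            for nb, ln in self.adj[v].items():
                if nb not in dist:
                    dist[nb] = dist[v] + ln
                    stack.append(nb)
        raise TreeError("disconnected tree")

    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """All pairwise leaf path distances (ids sorted)."""
        names = self.taxa
        n = len(names)
        D = np.zeros((n, n))
        for i in range(n):
            dist = {self.node_of(names[i]): 0.0}
            stack = [self.node_of(names[i])]
            while stack:
                v = stack.pop()
                for nb, ln in self.adj[v].items():
                    if nb not in dist:
                        dist[nb] = dist[v] + ln
                        stack.append(nb)
            for j in range(n):
                D[i, j] = dist[self.node_of(names[j])]
        return names, D

    # -- newick --------------------------------------------------------

    def to_newick(self, with_support: bool = True) -> str:
        if self.n_leaves == 0:
            return ";"
        if self.n_leaves == 1:
            return f"{self.taxa[0]};"
        internal = [v for v in self.adj if not self.is_leaf(v)]
        root = max(internal, key=lambda v: (len(self.adj[v]), -v)) if internal else None
        if root is None:  # two-leaf tree
            (a, b, ln) = self.edges()[0]
            na, nb = sorted((self.leaf_name[a], self.leaf_name[b]))
            return f"({na}:{ln:.10g},{nb}:0);"
        sides = self._leafsets() if with_support and self.support else {}

        def fmt(node: int, parent: int) -> str:
            ln = self.adj[parent][node]
            if self.is_leaf(node):
                return f"{self.leaf_name[node]}:{ln:.10g}"
            inner = ",".join(fmt(nb, node) for nb in sorted(self.adj[node]) if nb != parent)
            label = ""
            if with_support and self.support:
                side = sides.get((parent, node)) or sides.get((node, parent))
                if side is not None:
                    key = self.canonical_split(side)
                    if key in self.support:
                        label = f"{self.support[key]:.10g}"
            return f"({inner}){label}:{ln:.10g}"

        inner = ",".join(fmt(nb, root) for nb in sorted(self.adj[root]))
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string; numeric internal labels become supports."""
        text = text.strip()
        if not text.endswith(";"):
            raise TreeError("newick must end with ';'")
        s = text[:-1]
        t = cls()
        pos = 0
        # (child, parent, value): the label names the edge above the child
        pending_support: list[tuple[int, int, float]] = []

        def parse_clade(parent: int | None) -> tuple[int, float]:
            nonlocal pos
            if s[pos] == "(":
                pos += 1
                node = t.add_node()
                while True:
                    child, ln = parse_clade(node)
                    t.add_edge(node, child, max(ln, 0.0))
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                label, length = parse_label_length()
                if label and parent is not None:
                    try:
                        pending_support.append((node, parent, float(label)))
                    except ValueError:
                        pass
                return node, length
            label, length = parse_label_length()
            if not label:
                raise TreeError(f"expected leaf label at position {pos}")
            return t.add_node(name=label), length

        def parse_label_length() -> tuple[str, float]:
            nonlocal pos
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            label = s[start:pos].strip()
            length = 0.0
            if pos < len(s) and s[pos] == ":":
                pos += 1
                start = pos
                while pos < len(s) and s[pos] not in ",();":
                    pos += 1
                length = float(s[start:pos])
            return label, length

        root, _ = parse_clade(None)
        # Collapse a rooted-style degree-2 root into an unrooted edge.
        removed_root, replacement = None, {}
        if not t.is_leaf(root) and len(t.adj[root]) == 2:
            (a, la), (b, lb) = list(t.adj[root].items())
            t.remove_node(root)
            t.add_edge(a, b, la + lb)
            removed_root, replacement = root, {a: b, b: a}
        if t.n_leaves >= 4:
            for child, parent, val in pending_support:
                if child not in t.adj:
                    continue
                if parent == removed_root:
                    parent = replacement[child]
                # leaves on the child's side of the (child, parent) edge
                side, stack, seen = set(), [child], {parent, child}
                while stack:
                    v = stack.pop()
                    if t.is_leaf(v):
                        side.add(t.leaf_name[v])
                    for nb in t.adj[v]:
                        if nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
                if 2 <= len(side) <= t.n_leaves - 2:
                    t.support[t.canonical_split(side)] = val
        names = list(t.leaf_name.values())
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf labels in newick")
        return t
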