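"""Lightweight unrooted phylogenetic trees.

Trees are stored as an undirected adjacency map with branch lengths in
expected substitutions per site.  Leaves carry unique string labels.  The
class supports exactly what the inference and attribution code needs —
Newick round-tripping (via dendropy), path lengths, pendant statistics,
edge subdivision/leaf attachment, and split extraction — without imposing a
rooted view.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

__all__ = ["PhyloTree"]


class PhyloTree:
    """Unrooted tree over labelled leaves with non-negative branch lengths."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.label: dict[int, str] = {}
        self._node_of: dict[str, int] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        n = self._next_id
        self._next_id += 1
        self.adj[n] = {}
        if label is not None:
            if label in self._node_of:
                raise ValueError(f"duplicate leaf label {label!r}")
            self.label[n] = label
            self._node_of[label] = n
        return n

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0:
            raise ValueError("branch length must be non-negative")
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        t.label = dict(self.label)
        t._node_of = dict(self._node_of)
        t._next_id = self._next_id
        return t

    # -- basic queries ----------------------------------------------------

    def degree(self, n: int) -> int:
        return len(self.adj[n])

    def is_leaf(self, n: int) -> bool:
        return n in self.label

    @property
    def leaves(self) -> list[int]:
        return [n for n in self.adj if n in self.label]

    @property
    def leaf_names(self) -> list[str]:
        return [self.label[n] for n in self.leaves]

    def node_of(self, label: str) -> int:
        return self._node_of[label]

    def edges(self) -> list[tuple[int, int, float]]:
        seen = []
        for u, nbrs in self.adj.items():
            for v, ln in nbrs.items():
                if u < v:
                    seen.append((u, v, ln))
        return seen

    def internal_edges(self) -> list[tuple[int, int]]:
        """Edges with an internal (unlabelled) node on both ends."""
        return [(u, v) for u, v, _ in self.edges()
                if not self.is_leaf(u) and not self.is_leaf(v)]

    def total_length(self) -> float:
        return sum(ln for _, _, ln in self.edges())

    # -- metrics ----------------------------------------------------------

    def path_lengths_from(self, start: int) -> dict[int, float]:
        """Path length (sum of branch lengths) from ``start`` to every node."""
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, ln in self.adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        return dist

    def pendant_lengths(self) -> dict[str, float]:
        """Branch length of each leaf's pendant edge, keyed by leaf label."""
        return {self.label[n]: next(iter(self.adj[n].values()))
                for n in self.leaves}

    def median_pendant_length(self) -> float:
        vals = sorted(self.pendant_lengths().values())
        m = len(vals)
        if m == 0:
            raise ValueError("tree has no leaves")
        mid = m // 2
        return vals[mid] if m % 2 else 0.5 * (vals[mid - 1] + vals[mid])

    # -- topology edits ---------------------------------------------------

    def subdivide_edge(self, u: int, v: int, dist_from_u: float) -> int:
        """Insert a new internal node on edge (u, v) at ``dist_from_u``."""
        length = self.adj[u][v]
        if not 0.0 <= dist_from_u <= length:
            raise ValueError("subdivision point outside edge")
        self.remove_edge(u, v)
        w = self.add_node()
        self.add_edge(u, w, dist_from_u)
        self.add_edge(w, v, length - dist_from_u)
        return w

    def attach_leaf(self, u: int, v: int, dist_from_u: float,
                    pendant_length: float, label: str) -> int:
        """Attach a new labelled leaf onto edge (u, v); returns the leaf node."""
        w = self.subdivide_edge(u, v, dist_from_u)
        leaf = self.add_node(label)
        self.add_edge(w, leaf, pendant_length)
        return leaf

    def relabel_leaf(self, old: str, new: str) -> None:
        n = self._node_of.pop(old)
        if new in self._node_of:
            raise ValueError(f"duplicate leaf label {new!r}")
        self.label[n] = new
        self._node_of[new] = n

    def prune_leaf(self, label: str) -> None:
        """Remove a leaf and smooth out the attachment node it leaves behind."""
        n = self._node_of.pop(label)
        (attach,) = self.adj[n]
        self.remove_edge(n, attach)
        del self.adj[n], self.label[n]
        self.suppress_degree_two()

    def suppress_degree_two(self) -> None:
        """Merge edges through unlabelled degree-2 nodes (summing lengths)."""
        for n in list(self.adj):
            if n not in self.label and self.degree(n) == 2:
                (a, la), (b, lb) = self.adj[n].items()
                self.remove_edge(n, a)
                self.remove_edge(n, b)
                del self.adj[n]
                self.add_edge(a, b, la + lb)

    # -- splits -----------------------------------------------------------

    def side_leaves(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the ``u`` side of edge (u, v)."""
        seen = {u}
        stack = [u]
        out = []
        while stack:
            x = stack.pop()
            if x in self.label:
                out.append(self.label[x])
            for y in self.adj[x]:
                if y not in seen and not (x == u and y == v):
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self, include_trivial: bool = False
                     ) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """(side_a, side_b, branch_length) per edge; trivial = pendant edges."""
        all_leaves = frozenset(self.leaf_names)
        out = []
        for u, v, ln in self.edges():
            a = self.side_leaves(u, v)
            b = all_leaves - a
            if not include_trivial and (len(a) < 2 or len(b) < 2):
                continue
            out.append((a, b, ln))
        return out

    def topology_id(self) -> frozenset[frozenset[str]]:
        """Set of nontrivial splits (smaller side), for topology comparison."""
        return frozenset(min(a, b, key=lambda s: (len(s), sorted(s)))
                         for a, b, _ in self.bipartitions())

    # -- Newick -----------------------------------------------------------

    def to_newick(self) -> str:
        if len(self.adj) == 1:
            (n,) = self.adj
            return f"{self.label.get(n, '')};"
        root = next((n for n in self.adj if not self.is_leaf(n)), None)
        if root is None:  # two-leaf tree
            u, v = list(self.adj)
            ln = self.adj[u][v]
            return f"({self.label[u]}:{ln:.6g},{self.label[v]}:0);"

        def fmt(n: int, parent: int | None) -> str:
            children = [m for m in self.adj[n] if m != parent]
            if not children:
                return self.label[n]
            inner = ",".join(
                f"{fmt(m, n)}:{self.adj[n][m]:.6g}" for m in children)
            return f"({inner})"

        return fmt(root, None) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def read_newick(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        t = cls()
        node_map: dict = {}
        for nd in dtree.preorder_node_iter():
            label = nd.taxon.label if nd.taxon is not None else None
            node_map[nd] = t.add_node(label)
            if nd.parent_node is not None:
                ln = nd.edge.length if nd.edge.length is not None else 0.0
                t.add_edge(node_map[nd.parent_node], node_map[nd], float(ln))
        t.suppress_degree_two()
        return t

    def to_dendropy(self, taxon_namespace: "dendropy.TaxonNamespace | None" = None
                    ) -> "dendropy.Tree":
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True,
                                 taxon_namespace=taxon_namespace)

    def __repr__(self) -> str:
        return f"PhyloTree(n_leaves={len(self.leaves)})"
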