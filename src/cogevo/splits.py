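"""Split systems and Z-closure supernetworks from partial trees.

Every internal edge of an unrooted tree induces a bipartition (split) of
its leaf set.  Combining splits harvested from several gene trees — whose
leaf sets may differ — yields a split system over the union taxon set;
partial splits are extended to that universe with the Z-closure rule, and
pairwise incompatibility among the resulting full splits measures
reticulation (tree-like data has none).  The assembled system is written as
a SplitsTree-readable NEXUS splits block; drawing the planar network is
delegated to such viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .tree import PhyloTree

__all__ = [
    "Split",
    "SplitSet",
    "tree_to_splits",
    "trees_to_splits",
    "z_closure",
    "filter_supernetwork",
    "compatibility_stats",
    "splits_to_tree",
    "write_splits_nexus",
]


@dataclass(frozen=True)
class Split:
    """Weighted (possibly partial) bipartition in canonical orientation:
    ``side_a`` holds the lexicographically smallest covered taxon."""

    side_a: frozenset[str]
    side_b: frozenset[str]
    weight: float = 0.0  # summed branch lengths of contributing edges
    support: int = 1     # number of source trees inducing the split

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a split must be non-empty")
        if self.side_a & self.side_b:
            raise ValueError("split sides must be disjoint")
        if self.weight < 0:
            raise ValueError("split weight must be non-negative")
        if min(self.side_a) > min(self.side_b):
            a, b = self.side_a, self.side_b
            object.__setattr__(self, "side_a", b)
            object.__setattr__(self, "side_b", a)

    @property
    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        return (self.side_a, self.side_b)

    @property
    def covered(self) -> frozenset[str]:
        return self.side_a | self.side_b

    def is_full(self, universe: frozenset[str]) -> bool:
        return self.covered == universe

    def is_trivial(self) -> bool:
        return len(self.side_a) < 2 or len(self.side_b) < 2


class SplitSet:
    """Deduplicated collection of splits over a taxon universe.

    Re-adding an existing split merges it: weights sum and supports
    accumulate.
    """

    def __init__(self, universe: frozenset[str] | set[str],
                 splits: list[Split] = (), n_trees: int = 0):
        self.universe = frozenset(universe)
        self.n_trees = n_trees
        self._by_key: dict = {}
        for s in splits:
            self.add(s)

    def add(self, split: Split) -> None:
        if not split.covered <= self.universe:
            raise ValueError("split covers taxa outside the universe")
        old = self._by_key.get(split.key)
        if old is None:
            self._by_key[split.key] = split
        else:
            self._by_key[split.key] = Split(
                split.side_a, split.side_b,
                weight=old.weight + split.weight,
                support=old.support + split.support)

    @property
    def splits(self) -> list[Split]:
        return sorted(self._by_key.values(),
                      key=lambda s: (sorted(s.side_a), sorted(s.side_b)))

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self.splits)

    def keys(self) -> frozenset:
        return frozenset(self._by_key)


def tree_to_splits(tree: PhyloTree, include_trivial: bool = False) -> SplitSet:
    """One split per internal edge, weighted by branch length."""
    if len(tree.leaves) < 4:
        raise ValueError("need at least 4 leaves to extract splits")
    universe = frozenset(tree.leaf_names)
    ss = SplitSet(universe, n_trees=1)
    for a, b, ln in tree.bipartitions(include_trivial=include_trivial):
        ss.add(Split(a, b, weight=ln, support=1))
    return ss


def trees_to_splits(trees: list[PhyloTree]) -> SplitSet:
    """Harvest (partial) splits from trees with possibly different leaf sets."""
    universe = frozenset().union(*(frozenset(t.leaf_names) for t in trees))
    ss = SplitSet(universe, n_trees=len(trees))
    for t in trees:
        for a, b, ln in t.bipartitions():
            ss.add(Split(a, b, weight=ln, support=1))
    return ss


# ---------------------------------------------------------------------------
# Z-closure
# ---------------------------------------------------------------------------

def _extend_pair(s1: Split, s2: Split) -> tuple[Split, Split] | None:
    """Apply the Z-rule to the ordered pair (s1, s2) if it fires.

    With s1 = A1|B1 and s2 = A2|B2 such that A1 and A2 meet, B1 and B2
    meet, and A1 avoids B2: extend to A1|(B1 u B2) and (A1 u A2)|B2.
    Returns None when the rule does not apply or changes nothing.
    """
    for a1, b1 in ((s1.side_a, s1.side_b), (s1.side_b, s1.side_a)):
        for a2, b2 in ((s2.side_a, s2.side_b), (s2.side_b, s2.side_a)):
            if (a1 & a2) and (b1 & b2) and not (a1 & b2):
                n1 = Split(a1, b1 | b2, weight=s1.weight, support=s1.support)
                n2 = Split(a1 | a2, b2, weight=s2.weight, support=s2.support)
                if n1.key != s1.key or n2.key != s2.key:
                    return n1, n2
    return None


def z_closure(splits: SplitSet, max_passes: int = 10_000) -> SplitSet:
    """Z-closure of a partial split system.

    Repeatedly sweeps all ordered split pairs in deterministic canonical
    order, replacing a pair by its extensions whenever the rule fires,
    until a fixpoint; the result is deduplicated and idempotent under
    re-application.
    """
    work = list(splits.splits)
    for _ in range(max_passes):
        changed = False
        i = 0
        while i < len(work):
            j = 0
            while j < len(work):
                if i != j:
                    ext = _extend_pair(work[i], work[j])
                    if ext is not None:
                        work[i], work[j] = ext
                        changed = True
                j += 1
            i += 1
        if not changed:
            break
        work.sort(key=lambda s: (sorted(s.side_a), sorted(s.side_b)))
    else:
        raise RuntimeError(
            f"Z-closure did not reach a fixpoint within {max_passes} passes")
    return SplitSet(splits.universe, work, n_trees=splits.n_trees)


def filter_supernetwork(splits: SplitSet, min_trees: int = 1) -> SplitSet:
    """Retain splits induced by at least ``min_trees`` source trees.

    The weight of a retained split becomes the mean of its contributing
    edge weights.
    """
    if min_trees < 1:
        raise ValueError("min_trees must be >= 1")
    out = SplitSet(splits.universe, n_trees=splits.n_trees)
    for s in splits:
        if s.support >= min_trees:
            out.add(Split(s.side_a, s.side_b,
                          weight=s.weight / s.support, support=s.support))
    return out


def compatibility_stats(splits: SplitSet) -> tuple[int, bool]:
    """(number of incompatible split pairs, whether the system is tree-like).

    Two full splits are incompatible iff all four side intersections are
    non-empty.  Partial splits are rejected; close the system first.
    """
    items = splits.splits
    for s in items:
        if not s.is_full(splits.universe):
            raise ValueError("compatibility requires full splits; "
                             "apply z_closure first")
    n_bad = 0
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            s, t = items[i], items[j]
            if (s.side_a & t.side_a and s.side_a & t.side_b
                    and s.side_b & t.side_a and s.side_b & t.side_b):
                n_bad += 1
    return n_bad, n_bad == 0


def splits_to_tree(splits: SplitSet) -> PhyloTree:
    """Reconstruct the unrooted tree of a compatible full split system.

    Nontrivial splits become internal edges carrying the split weight;
    pendant edges get zero length unless trivial splits are present.
    """
    n_bad, _ = compatibility_stats(splits)
    if n_bad:
        raise ValueError("split system is not compatible")
    taxa = sorted(splits.universe)
    anchor = taxa[0]
    # represent each split as the cluster not containing the anchor
    clusters: list[tuple[frozenset[str], float]] = []
    pendant_weight = {t: 0.0 for t in taxa}
    for s in splits:
        cl = s.side_b if anchor in s.side_a else s.side_a
        if len(cl) == len(taxa) - 1:  # trivial split of the anchor
            pendant_weight[anchor] = s.weight
            continue
        if len(cl) == 1:
            pendant_weight[next(iter(cl))] = s.weight
            continue
        clusters.append((cl, s.weight))
    clusters.sort(key=lambda c: len(c[0]))

    tree = PhyloTree()
    root = tree.add_node()
    node_of_cluster: dict[frozenset[str], int] = {}
    # laminar family: attach largest first so children nest under parents
    attach_order = sorted(clusters, key=lambda c: -len(c[0]))
    parent_of: dict[frozenset[str], int] = {}
    placed: list[tuple[frozenset[str], int]] = []
    for cl, w in attach_order:
        parent = root
        for pcl, pnode in placed:
            if cl < pcl:
                parent = pnode
                break
        node = tree.add_node()
        tree.add_edge(parent, node, w)
        node_of_cluster[cl] = node
        placed.insert(0, (cl, node))
    for t in taxa:
        parent = root
        best = None
        for cl, node in placed:
            if t in cl and (best is None or len(cl) < len(best)):
                best, parent = cl, node
        leaf = tree.add_node(t)
        tree.add_edge(parent, leaf, pendant_weight[t])
    tree.suppress_degree_two()
    return tree


# ---------------------------------------------------------------------------
# NEXUS export
# ---------------------------------------------------------------------------

def write_splits_nexus(splits: SplitSet, path: str | Path) -> None:
    """SplitsTree-readable NEXUS with TAXA and SPLITS blocks."""
    taxa = sorted(splits.universe)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    items = splits.splits
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(taxa)};",
        "    TAXLABELS",
    ]
    lines += [f"        '{t}'" for t in taxa]
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN SPLITS;",
        f"    DIMENSIONS NTAX={len(taxa)} NSPLITS={len(items)};",
        "    FORMAT LABELS=NO WEIGHTS=YES CONFIDENCES=NO;",
        "    MATRIX",
    ]
    for i, s in enumerate(items, start=1):
        members = " ".join(str(index[t]) for t in sorted(s.side_a,
                                                         key=index.get))
        lines.append(f"        [{i}] {s.weight:.6g} {members},")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def stats_json(splits: SplitSet, path: str | Path | None = None) -> str:
    n_bad, tree_like = compatibility_stats(splits)
    payload = json.dumps({
        "n_taxa": len(splits.universe),
        "n_splits": len(splits),
        "n_source_trees": splits.n_trees,
        "n_pairs_incompatible": n_bad,
        "is_tree_like": tree_like,
    }, indent=2)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload
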