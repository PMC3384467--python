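"""Sister-clade donor attribution of focal alleles and category tallies.

Visual tree inspection — "which clade does the focal allele sit inside?" —
is made algorithmic: the focal leaf's attachment node is located, the
adjacent subtree with the smallest mean path distance to the focal leaf is
taken as the sister group, and the category composition of its nearest
leaves decides the donor code.  A purity threshold separates clean
singleton codes (P, B, T, HA, A) from combination codes, and a distance
cutoff relative to the tree's median pendant branch length declares
long-branch orphans NC ("no cluster").  All thresholds are explicit
parameters of :class:`AssignmentParams`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .taxa import Category, TaxonSet
from .tree import PhyloTree

__all__ = [
    "AssignmentParams",
    "DonorCall",
    "CategoryTally",
    "assign_donor",
    "tally_categories",
    "SUMMARY_CLASSES",
]

#: Summary classes of the headline tally, in reporting order.
SUMMARY_CLASSES = (
    "other_bacteria_hgt",
    "proteobacteria_vertical",
    "archaeal_hgt",
    "no_cluster",
)

_BACTERIAL_CODES = {"P", "B"}
_ARCHAEAL_CODES = {"T", "HA", "A"}


@dataclass(frozen=True)
class AssignmentParams:
    """Thresholds of the donor-attribution rule.

    purity_threshold
        Minimum share of the dominant category for a singleton code
        (otherwise a combination code is emitted).
    combination_share
        Minimum share for a category to enter a combination code.
    k_nearest
        Neighbour set is capped at this many nearest leaves of the sister
        subtree (by path distance).
    nc_pendant_multiplier
        NC is called when the nearest neighbour is farther than this
        multiple of the tree's median pendant branch length.
    """

    purity_threshold: float = 0.75
    combination_share: float = 0.25
    k_nearest: int = 10
    nc_pendant_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if not 0.5 < self.purity_threshold <= 1.0:
            raise ValueError("purity_threshold must be in (0.5, 1]")
        if not 0.0 < self.combination_share <= 0.5:
            raise ValueError("combination_share must be in (0, 0.5]")
        if self.k_nearest < 1:
            raise ValueError("k_nearest must be >= 1")
        if self.nc_pendant_multiplier <= 0:
            raise ValueError("nc_pendant_multiplier must be positive")


@dataclass(frozen=True)
class DonorCall:
    """Donor category call for one focal allele of one COG."""

    cog_id: str
    allele_id: str
    code: str  # "P", "B", "T", "HA", "A", a comma-joined combination, or "NC"
    neighbor_taxa: tuple[str, ...] = ()
    neighbor_purity: float = 0.0
    min_neighbor_distance: float = 0.0
    category_shares: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.code != "NC":
            parts = self.code.split(",")
            bad = [p for p in parts
                   if p not in _BACTERIAL_CODES | _ARCHAEAL_CODES]
            if bad:
                raise ValueError(f"unknown donor code component(s) {bad}")
            if parts != sorted(parts):
                raise ValueError("combination codes must be sorted")


def assign_donor(tree: PhyloTree, taxonomy: TaxonSet, focal_leaf: str,
                 params: AssignmentParams | None = None,
                 taxon_of: dict[str, str] | None = None,
                 cog_id: str = "") -> DonorCall:
    """Classify one focal allele by the category of its sister subtree.

    ``taxon_of`` maps leaf labels to taxon ids in ``taxonomy`` (identity by
    default).  Leaves mapping to a FOCAL-category taxon — the focal
    organism's other alleles — are excluded from neighbour candidacy, so
    paralogs never vote for their own category.
    """
    if params is None:
        params = AssignmentParams()
    if focal_leaf not in tree.leaf_names:
        raise ValueError(f"focal leaf {focal_leaf!r} absent from tree")
    taxon_of = taxon_of or {}

    def category(leaf: str) -> Category:
        tid = taxon_of.get(leaf, leaf)
        if tid not in taxonomy:
            raise ValueError(f"leaf {leaf!r} has no taxonomy entry")
        return taxonomy.category_of(tid)

    focal_node = tree.node_of(focal_leaf)
    attach = next(iter(tree.adj[focal_node]))
    dist = tree.path_lengths_from(focal_node)

    def eligible(leaves: frozenset[str]) -> list[str]:
        return [lf for lf in leaves
                if lf != focal_leaf and category(lf) is not Category.FOCAL]

    # adjacent subtrees at the attachment node, scored by mean distance
    subtrees = []
    for nbr in tree.adj[attach]:
        if nbr == focal_node:
            continue
        leaves = eligible(tree.side_leaves(nbr, attach))
        if leaves:
            mean_d = sum(dist[tree.node_of(lf)] for lf in leaves) / len(leaves)
            subtrees.append((mean_d, sorted(leaves)))
    if not subtrees:
        raise ValueError(f"no labelled neighbours for {focal_leaf!r}")
    subtrees.sort(key=lambda x: (x[0], x[1]))
    sister_leaves = subtrees[0][1]

    nearest = sorted(sister_leaves,
                     key=lambda lf: (dist[tree.node_of(lf)], lf))
    neighbors = nearest[:params.k_nearest]
    min_distance = dist[tree.node_of(neighbors[0])]

    shares: dict[str, float] = {}
    for lf in neighbors:
        code = category(lf).code
        shares[code] = shares.get(code, 0.0) + 1.0 / len(neighbors)
    purity = max(shares.values())

    delta = params.nc_pendant_multiplier * tree.median_pendant_length()
    if min_distance > delta:
        code = "NC"
    elif purity >= params.purity_threshold:
        code = max(shares, key=lambda c: (shares[c], c))
    else:
        parts = sorted(c for c, s in shares.items()
                       if s >= params.combination_share)
        code = ",".join(parts) if parts else max(
            shares, key=lambda c: (shares[c], c))

    return DonorCall(
        cog_id=cog_id, allele_id=focal_leaf, code=code,
        neighbor_taxa=tuple(taxon_of.get(lf, lf) for lf in neighbors),
        neighbor_purity=purity, min_neighbor_distance=min_distance,
        category_shares=shares,
    )


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

def summary_class_of(call: DonorCall) -> str:
    """Map a donor code to its headline summary class.

    P alone is vertical descent; B and purely bacterial combinations are
    other-bacteria HGT; archaeal codes and combinations are archaeal HGT;
    mixed bacterial/archaeal combinations go to the side with the larger
    summed share (ties to other-bacteria); NC is its own class.
    """
    if call.code == "NC":
        return "no_cluster"
    parts = call.code.split(",")
    if parts == ["P"]:
        return "proteobacteria_vertical"
    bact = [p for p in parts if p in _BACTERIAL_CODES]
    arch = [p for p in parts if p in _ARCHAEAL_CODES]
    if bact and not arch:
        return "other_bacteria_hgt"
    if arch and not bact:
        return "archaeal_hgt"
    if call.category_shares:
        b_share = sum(call.category_shares.get(p, 0.0) for p in bact)
        a_share = sum(call.category_shares.get(p, 0.0) for p in arch)
    else:
        b_share, a_share = float(len(bact)), float(len(arch))
    return "archaeal_hgt" if a_share > b_share else "other_bacteria_hgt"


@dataclass(frozen=True)
class CategoryTally:
    """Counts and fractions of calls per summary class."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n_total: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n_total": self.n_total,
            "counts": self.counts,
            "fractions": self.fractions,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def tally_categories(calls: list[DonorCall]) -> CategoryTally:
    """Figure-style tally of donor calls over the four summary classes."""
    if not calls:
        raise ValueError("no donor calls to tally")
    counts = {c: 0 for c in SUMMARY_CLASSES}
    for call in calls:
        counts[summary_class_of(call)] += 1
    n = len(calls)
    fractions = {c: counts[c] / n for c in SUMMARY_CLASSES}
    return CategoryTally(counts=counts, fractions=fractions, n_total=n)


def write_calls_tsv(calls: list[DonorCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cog_id\tallele_id\tcode\tpurity\tmin_neighbor_distance\n")
        for c in calls:
            fh.write(f"{c.cog_id}\t{c.allele_id}\t{c.code}\t"
                     f"{c.neighbor_purity:.4f}\t{c.min_neighbor_distance:.6g}\n")


def read_calls_tsv(path: str | Path) -> list[DonorCall]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                cog, allele, code, purity, dist = line.rstrip("\n").split("\t")
                out.append(DonorCall(cog, allele, code,
                                     neighbor_purity=float(purity),
                                     min_neighbor_distance=float(dist)))
    return out
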