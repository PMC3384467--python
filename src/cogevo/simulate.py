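"""Synthetic data with planted ground truth.

This module generates every input the analysis consumes: reference
taxonomies partitioned into the five clade categories, per-COG gene trees
in which the focal organism's alleles attach either vertically (inside the
Proteobacteria clade) or inside a planted donor clade (horizontal gene
transfer), protein alignments evolved site-independently under a reversible
amino-acid model, gapped columns, synthetic genomes with gene coordinate
tables, and batch-culture time series with the glucose-before-sucrose
uptake pattern seen in PHB production runs.

Species trees are clade-respecting by construction: the taxa of each
category form a pure-birth subtree grafted onto a fixed five-category
backbone, which is exactly the structure sister-clade donor attribution
assumes.  All randomness in each function flows from its explicit seed;
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import CogAlignment
from .genome import Gene, GenomeAnnotation
from .substitution import SubstitutionModel
from .taxa import CODE_TO_CATEGORY, REFERENCE_CATEGORIES, Category, \
    TaxonRecord, TaxonSet
from .tree import PhyloTree

__all__ = [
    "SimulationTruth",
    "simulate_taxonomy",
    "simulate_species_tree",
    "simulate_cog",
    "plan_cog_truths",
    "simulate_genome",
    "CultureParams",
    "CultureSeries",
    "simulate_batch_culture",
    "SUMMARY_CLASS_CODES",
]

_ID_PREFIX = {
    Category.PROTEO: "PRO",
    Category.OTHER_BACT: "OBA",
    Category.THERMO_ARCH: "THA",
    Category.HALO_ARCH: "HAR",
    Category.OTHER_ARCH: "OAR",
}

#: Donor codes drawn for each summary class when planting ground truth.
SUMMARY_CLASS_CODES = {
    "other_bacteria_hgt": ("B",),
    "proteobacteria_vertical": ("P",),
    "archaeal_hgt": ("T", "HA", "A"),
    "no_cluster": ("NC",),
}


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for one focal allele of one COG."""

    cog_id: str
    allele_id: str
    planted_code: str  # P, B, T, HA, A or NC
    donor_taxon_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_code not in {"P", "B", "T", "HA", "A", "NC"}:
            raise ValueError(f"unknown planted code {self.planted_code!r}")


def simulate_taxonomy(n_per_category: dict[Category, int],
                      seed: int) -> TaxonSet:
    """Reference taxon panel with the requested number of taxa per category."""
    for cat, n in n_per_category.items():
        if n < 1:
            raise ValueError(f"count for {cat} must be >= 1, got {n}")
        if cat not in REFERENCE_CATEGORIES:
            raise ValueError(f"{cat} is not a reference category")
    rng = np.random.default_rng(seed)
    records = []
    for cat in REFERENCE_CATEGORIES:
        n = n_per_category.get(cat, 0)
        for i in range(1, n + 1):
            # invented binomial-style names, deterministic per seed
            syllables = rng.choice(list("abcdefghilmnoprstu"), size=6)
            name = ("".join(syllables[:3]).capitalize() + "us "
                    + "".join(syllables[3:]) + "ii")
            records.append(TaxonRecord(
                taxon_id=f"{_ID_PREFIX[cat]}{i:02d}", name=name, category=cat))
    return TaxonSet(records)


# ---------------------------------------------------------------------------
# species trees and gene trees
# ---------------------------------------------------------------------------

def _yule_join(tree: PhyloTree, nodes: list[int], rng: np.random.Generator,
               branch_scale: float) -> int:
    """Pure-birth style joining of subtree roots; returns the clade root.

    Branch lengths are uniform on [0.5, 2] x ``branch_scale``: the random
    join order gives the Yule topology while the bounded lengths keep the
    tree's median pendant length stable, which keeps planted NC (long
    orphan branch) and planted donor-clade attachments unambiguous
    relative to the median-pendant NC cutoff used downstream.
    """
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = tree.add_node()
        tree.add_edge(parent, a,
                      float(rng.uniform(0.5 * branch_scale, 2 * branch_scale)))
        tree.add_edge(parent, b,
                      float(rng.uniform(0.5 * branch_scale, 2 * branch_scale)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def simulate_species_tree(taxa: TaxonSet, seed: int,
                          branch_scale: float = 0.08,
                          backbone_length: float = 0.4) -> PhyloTree:
    """Clade-respecting reference species tree.

    Taxa of each category form a pure-birth clade (branch lengths uniform
    on [0.5, 2] x ``branch_scale``) grafted onto a fixed backbone
    ``((PROTEO, OTHER_BACT), (THERMO, (HALO, OTHER)))`` whose edges have
    length ``backbone_length``.
    """
    rng = np.random.default_rng(seed)
    tree = PhyloTree()
    roots: dict[Category, int] = {}
    for cat in REFERENCE_CATEGORIES:
        ids = taxa.ids(cat)
        if not ids:
            continue
        leaves = [tree.add_node(t) for t in ids]
        roots[cat] = _yule_join(tree, leaves, rng, branch_scale)

    def graft(children: list[int]) -> int:
        if len(children) == 1:
            return children[0]
        parent = tree.add_node()
        for c in children:
            tree.add_edge(parent, c, backbone_length)
        return parent

    bact_parts = [roots[c] for c in (Category.PROTEO, Category.OTHER_BACT)
                  if c in roots]
    inner_parts = [roots[c] for c in (Category.HALO_ARCH, Category.OTHER_ARCH)
                   if c in roots]
    arch_parts = [roots[c] for c in (Category.THERMO_ARCH,) if c in roots]
    if inner_parts:
        arch_parts.append(graft(inner_parts))
    top = []
    if bact_parts:
        top.append(graft(bact_parts))
    if arch_parts:
        top.append(graft(arch_parts))
    if not top:
        raise ValueError("taxon set is empty")
    graft(top)
    tree.suppress_degree_two()
    return tree


def evolve_states(parent_states: np.ndarray, p: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample child states site-independently given a transition matrix."""
    cum = np.cumsum(p, axis=1)
    draws = rng.random(len(parent_states))
    return (draws[:, None] > cum[parent_states]).sum(axis=1).astype(np.int64)


def _category_pure_edges(tree: PhyloTree, taxa: TaxonSet,
                         category: Category) -> list[tuple[int, int]]:
    """Edges whose one side contains only (and not all) leaves of ``category``.

    These are the edges strictly inside the category's clade: pendant edges
    of its members and the internal edges among them, excluding the clade
    stem.  Sides containing focal alleles (leaves absent from the
    taxonomy) never qualify, so earlier attachments are skipped
    automatically.
    """
    want = set(taxa.ids(category))
    out = []
    for u, v, _ in tree.edges():
        for side_root, other in ((u, v), (v, u)):
            side = tree.side_leaves(side_root, other)
            if side and side <= want and side != want:
                out.append((side_root, other))
                break
    return out


def simulate_cog(taxa: TaxonSet, planted: SimulationTruth
                 | list[SimulationTruth], n_sites: int,
                 model: SubstitutionModel, gap_fraction: float = 0.0,
                 seed: int = 0, branch_scale: float = 0.08,
                 backbone_length: float = 0.4,
                 orphan_multiplier: float = 8.0,
                 focal_pendant_range: tuple[float, float] = (0.02, 0.12),
                 ) -> tuple[CogAlignment, PhyloTree]:
    """Simulate one COG: gene tree with planted focal alleles + alignment.

    The gene tree is the clade-respecting species tree with each focal
    allele attached inside its planted donor clade; NC (no-cluster) alleles
    hang from a deliberately long pendant branch (``orphan_multiplier``
    times the median pendant length).  One root sequence is drawn from the
    model's equilibrium frequencies and evolved site-independently down the
    tree via ``exp(Q t)``; afterwards a ``gap_fraction`` of columns is
    masked with gaps in a random subset of members.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0.0 <= gap_fraction < 1.0:
        raise ValueError("gap_fraction must be in [0, 1)")
    truths = [planted] if isinstance(planted, SimulationTruth) else list(planted)
    if not truths:
        raise ValueError("at least one planted allele required")
    cog_id = truths[0].cog_id
    rng = np.random.default_rng(seed)

    tree = simulate_species_tree(taxa, seed=int(rng.integers(2**31)),
                                 branch_scale=branch_scale,
                                 backbone_length=backbone_length)
    taxon_of = {t: t for t in taxa.ids()}

    for truth in truths:
        if truth.planted_code == "NC":
            candidates = tree.edges()
            u, v, ln = candidates[int(rng.integers(len(candidates)))]
            pendant = orphan_multiplier * tree.median_pendant_length()
        else:
            category = CODE_TO_CATEGORY[truth.planted_code]
            if len(taxa.ids(category)) < 4:
                raise ValueError(
                    f"need >= 4 taxa in donor category {category.value}")
            candidates = _category_pure_edges(tree, taxa, category)
            u, v = candidates[int(rng.integers(len(candidates)))]
            ln = tree.adj[u][v]
            lo, hi = focal_pendant_range
            pendant = float(rng.uniform(lo, hi))
        pos = float(rng.uniform(0.0, ln)) if ln > 0 else 0.0
        tree.attach_leaf(u, v, pos, pendant, truth.allele_id)
        taxon_of[truth.allele_id] = "FOCAL"

    # evolve one root sequence down the tree
    root = next(n for n in tree.adj if not tree.is_leaf(n))
    states: dict[int, np.ndarray] = {
        root: rng.choice(20, size=n_sites, p=model.frequencies)}
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        for child, t in tree.adj[node].items():
            if child == parent:
                continue
            states[child] = evolve_states(
                states[node], model.transition_matrix(t), rng)
            stack.append((child, node))

    from .wag_data import AMINO_ACIDS
    leaf_order = sorted(tree.leaves, key=lambda n: tree.label[n])
    ids = [tree.label[n] for n in leaf_order]
    chars = np.array(list(AMINO_ACIDS))
    seq_mat = np.vstack([chars[states[n]] for n in leaf_order])

    n_gap_cols = int(round(gap_fraction * n_sites))
    if n_gap_cols:
        cols = rng.choice(n_sites, size=n_gap_cols, replace=False)
        for c in cols:
            mask = rng.random(len(ids)) < 0.3
            if not mask.any():
                mask[int(rng.integers(len(ids)))] = True
            seq_mat[mask, c] = "-"

    seqs = ["".join(row) for row in seq_mat]
    aln = CogAlignment(cog_id, ids, seqs, taxon_of)
    return aln, tree


def plan_cog_truths(n_cogs: int, class_fractions: dict[str, float],
                    seed: int, alleles_per_cog: int = 1,
                    cog_prefix: str = "SCOG",
                    stratified: bool = True) -> list[SimulationTruth]:
    """Plant donor codes for a batch of COGs according to class fractions.

    ``class_fractions`` maps the four summary classes (keys of
    ``SUMMARY_CLASS_CODES``) to proportions summing to 1.  With
    ``stratified=True`` (the default) the planted counts realise the
    fractions exactly (largest-remainder rounding) and only the assignment
    of codes to COGs is shuffled, so downstream recovery error measures
    the pipeline rather than sampling noise.  With ``stratified=False``
    each allele's class is drawn independently (multinomial planting).
    Within the archaeal class the three archaeal codes are spread evenly
    (stratified) or drawn uniformly (multinomial).
    """
    classes = list(SUMMARY_CLASS_CODES)
    probs = np.array([class_fractions.get(c, 0.0) for c in classes])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_total = n_cogs * alleles_per_cog

    codes: list[str] = []
    if stratified:
        base = np.floor(probs * n_total).astype(int)
        remainder = probs * n_total - base
        short = n_total - int(base.sum())
        for k in np.argsort(-remainder)[:short]:
            base[k] += 1
        for cls, count in zip(classes, base):
            class_codes = SUMMARY_CLASS_CODES[cls]
            codes.extend(class_codes[i % len(class_codes)]
                         for i in range(count))
        rng.shuffle(codes)
    else:
        for _ in range(n_total):
            cls = classes[int(rng.choice(len(classes), p=probs))]
            class_codes = SUMMARY_CLASS_CODES[cls]
            codes.append(class_codes[int(rng.integers(len(class_codes)))])

    truths = []
    for i in range(1, n_cogs + 1):
        cog_id = f"{cog_prefix}{i:04d}"
        for a in range(1, alleles_per_cog + 1):
            truths.append(SimulationTruth(
                cog_id=cog_id, allele_id=f"{cog_id}_A{a}",
                planted_code=codes.pop(0), seed=int(rng.integers(2**31))))
    return truths


def write_truth_tsv(truths: list[SimulationTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cog_id\tallele_id\tplanted_code\tseed\n")
        for t in truths:
            fh.write(f"{t.cog_id}\t{t.allele_id}\t{t.planted_code}\t{t.seed}\n")


def read_truth_tsv(path: str | Path) -> list[SimulationTruth]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                cog, allele, code, seed = line.rstrip("\n").split("\t")
                out.append(SimulationTruth(cog, allele, code, seed=int(seed)))
    return out


# ---------------------------------------------------------------------------
# synthetic genomes
# ---------------------------------------------------------------------------

def simulate_genome(length: int, n_genes: int, gc_target: float, seed: int,
                    gene_length_range: tuple[int, int] = (300, 1500),
                    contig_id: str = "contig1",
                    ) -> tuple[str, GenomeAnnotation]:
    """IID genome sequence at a target GC plus non-overlapping gene intervals."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must be a fraction")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2,
                  (1 - gc_target) / 2])
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    sequence = "".join(bases)

    genes: list[Gene] = []
    if n_genes > 0:
        lo, hi = gene_length_range
        if n_genes * lo > length:
            raise ValueError(
                f"{n_genes} genes of >= {lo} bp do not fit in {length} bp")
        hi = max(min(hi, length // n_genes), lo)
        lengths = rng.integers(lo, hi + 1, size=n_genes)
        slack = length - int(lengths.sum())
        # distribute the slack over n_genes + 1 intergenic gaps
        gaps = rng.multinomial(slack, np.full(n_genes + 1, 1 / (n_genes + 1)))
        pos = 0
        for i, glen in enumerate(lengths):
            pos += int(gaps[i])
            start = pos + 1
            end = pos + int(glen)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"gene{i + 1:05d}", start, end, strand))
            pos = end
    return sequence, GenomeAnnotation(contig_id, length, genes)


def write_genome_fasta(sequence: str, contig_id: str,
                       path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig_id}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# batch cultures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CultureParams:
    """Two-substrate batch-culture parameters (defaults: the PHB production
    run on 1.5 % w/v sucrose + 1 % w/v glucose with limiting glutamate).

    Growth requires the nitrogen source (monosodium glutamate, MSG); once
    MSG is depleted growth stops and PHB accumulates, drawing on glucose
    preferentially — sucrose uptake is repressed while glucose exceeds
    ``glucose_repression_threshold``.
    """

    sucrose_0: float = 15.0        # g/L
    glucose_0: float = 10.0        # g/L
    msg_0: float = 2.0             # g/L
    rcm_0: float = 0.2             # g/L inoculum (residual cell mass)
    phb_0: float = 0.0             # g/L
    mu_max: float = 0.45           # 1/h
    k_n: float = 0.05              # g/L MSG half-saturation for growth
    k_s: float = 0.2               # g/L substrate half-saturation
    y_xn: float = 2.2              # g RCM per g MSG
    y_xs: float = 0.45             # g RCM per g substrate (growth)
    q_phb: float = 0.045           # g PHB per g RCM per h under N limitation
    y_ps: float = 0.35             # g PHB per g substrate
    k_n_repression: float = 0.05   # g/L MSG below which PHB synthesis is on
    glucose_repression_threshold: float = 1.0  # g/L
    noise_sd: float = 0.0          # lognormal sd on sampled biomass/PHB

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")


@dataclass
class CultureSeries:
    """Sampled batch-culture time series (g/L against hours)."""

    t_h: np.ndarray
    cdw_gL: np.ndarray
    phb_gL: np.ndarray
    glucose_gL: np.ndarray
    sucrose_gL: np.ndarray
    msg_gL: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.t_h, self.cdw_gL, self.phb_gL, self.glucose_gL,
                  self.sucrose_gL, self.msg_gL]
        n = len(self.t_h)
        if any(len(a) != n for a in arrays):
            raise ValueError("series columns must have equal length")
        if np.any(np.diff(self.t_h) <= 0):
            raise ValueError("time points must be strictly increasing")
        if any(np.any(np.asarray(a) < 0) for a in arrays[1:]):
            raise ValueError("concentrations must be non-negative")
        if np.any(self.phb_gL > self.cdw_gL + 1e-9):
            raise ValueError("PHB may not exceed CDW")

    @property
    def rcm_gL(self) -> np.ndarray:
        return self.cdw_gL - self.phb_gL

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({
            "t_h": self.t_h, "cdw_gL": self.cdw_gL, "phb_gL": self.phb_gL,
            "glucose_gL": self.glucose_gL, "sucrose_gL": self.sucrose_gL,
            "msg_gL": self.msg_gL,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CultureSeries":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(*(df[c].to_numpy(dtype=float) for c in
                     ("t_h", "cdw_gL", "phb_gL", "glucose_gL", "sucrose_gL",
                      "msg_gL")))


def simulate_batch_culture(params: CultureParams | None = None,
                           horizon: float = 33.0, dt: float = 0.5,
                           seed: int = 0) -> CultureSeries:
    """Euler-integrated two-substrate batch culture sampled every ``dt`` h.

    State variables are clamped non-negative at every step and
    CDW = RCM + PHB holds identically at every sampled point.
    """
    if params is None:
        params = CultureParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    h = min(dt, 0.02)
    n_sub = max(1, int(round(dt / h)))
    h = dt / n_sub

    x, phb = params.rcm_0, params.phb_0
    glc, suc, msg = params.glucose_0, params.sucrose_0, params.msg_0
    times = [0.0]
    rows = [(x, phb, glc, suc, msg)]
    n_steps = int(round(horizon / dt))
    for step in range(n_steps):
        for _ in range(n_sub):
            s_tot = glc + suc
            mu = (params.mu_max * msg / (params.k_n + msg)
                  * s_tot / (params.k_s + s_tot)) if s_tot > 0 else 0.0
            growth = mu * x * h
            growth = min(growth, params.y_xn * msg, params.y_xs * s_tot)
            dn = growth / params.y_xn if params.y_xn > 0 else 0.0
            ds = growth / params.y_xs if params.y_xs > 0 else 0.0
            # parallel assimilation during growth, split by availability
            dglc_g = ds * (glc / s_tot) if s_tot > 0 else 0.0
            dsuc_g = ds - dglc_g

            n_switch = params.k_n_repression / (params.k_n_repression + msg) \
                if msg > 0 else 1.0
            s_for_phb = glc if glc > params.glucose_repression_threshold \
                else s_tot
            dphb = (params.q_phb * x * n_switch
                    * s_for_phb / (params.k_s + s_for_phb)) * h \
                if s_for_phb > 0 else 0.0
            dphb = min(dphb, params.y_ps * s_tot)
            ds_p = dphb / params.y_ps if params.y_ps > 0 else 0.0
            if glc > params.glucose_repression_threshold:
                dglc_p, dsuc_p = ds_p, 0.0
            else:
                frac = glc / params.glucose_repression_threshold \
                    if params.glucose_repression_threshold > 0 else 0.0
                dglc_p = ds_p * frac
                dsuc_p = ds_p - dglc_p

            x = max(x + growth, 0.0)
            phb = max(phb + dphb, 0.0)
            msg = max(msg - dn, 0.0)
            glc = max(glc - dglc_g - dglc_p, 0.0)
            suc = max(suc - dsuc_g - dsuc_p, 0.0)
        times.append((step + 1) * dt)
        rows.append((x, phb, glc, suc, msg))

    arr = np.array(rows)
    x_s, phb_s = arr[:, 0].copy(), arr[:, 1].copy()
    if params.noise_sd > 0:
        x_s *= rng.lognormal(0.0, params.noise_sd, size=len(x_s))
        phb_s *= rng.lognormal(0.0, params.noise_sd, size=len(phb_s))
    return CultureSeries(
        t_h=np.array(times),
        cdw_gL=x_s + phb_s,
        phb_gL=phb_s,
        glucose_gL=arr[:, 2],
        sucrose_gL=arr[:, 3],
        msg_gL=arr[:, 4],
    )
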