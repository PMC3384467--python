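"""End-to-end reproducible runs: simulate -> filter -> infer -> assign ->
tally -> pathway -> supernetwork, with a checksummed manifest.

A run is fully determined by its :class:`RunConfig` (including the seed):
two runs with the same config produce byte-identical stage outputs and
therefore identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .donor import AssignmentParams, DonorCall, assign_donor, \
    tally_categories, write_calls_tsv
from .pathway import PathwayStep, annotate_pathway, default_pathway_steps, \
    write_annotations_tsv
from .phylo import infer_tree
from .simulate import plan_cog_truths, simulate_cog, simulate_taxonomy, \
    write_truth_tsv
from .splits import filter_supernetwork, stats_json, trees_to_splits, \
    write_splits_nexus, z_closure
from .substitution import wag
from .taxa import Category, REFERENCE_CATEGORIES, TaxonRecord, TaxonSet
from .tree import PhyloTree

logger = logging.getLogger("cogevo.pipeline")

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

_FOCAL_TAXON = TaxonRecord("FOCAL", "focal organism", Category.FOCAL)


@dataclass
class RunConfig:
    """Configuration of one synthetic pipeline run."""

    seed: int = 0
    outdir: str = "cogevo_run"
    n_cogs: int = 20
    alleles_per_cog: int = 1
    n_sites: int = 300
    gap_fraction: float = 0.05
    n_per_category: dict[str, int] = field(default_factory=lambda: {
        c.value: 6 for c in REFERENCE_CATEGORIES})
    class_fractions: dict[str, float] = field(default_factory=lambda: {
        "other_bacteria_hgt": 0.44,
        "proteobacteria_vertical": 0.34,
        "archaeal_hgt": 0.13,
        "no_cluster": 0.09,
    })
    nni_rounds: int = 1
    purity_threshold: float = 0.75
    combination_share: float = 0.25
    k_nearest: int = 10
    nc_pendant_multiplier: float = 5.0
    min_trees: int = 1
    n_supernetwork_trees: int = 6

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"class fractions must sum to 1, got {total:.6g}")
        if self.n_cogs < 1:
            raise ValueError("n_cogs must be >= 1")
        if self.alleles_per_cog < 1:
            raise ValueError("alleles_per_cog must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.nni_rounds < 0 or self.min_trees < 1:
            raise ValueError("invalid search/filter settings")
        for cat, n in self.n_per_category.items():
            Category(cat)
            if n < 1:
                raise ValueError(f"need >= 1 taxon in category {cat}")
        self.assignment_params()  # validates thresholds

    def assignment_params(self) -> AssignmentParams:
        return AssignmentParams(
            purity_threshold=self.purity_threshold,
            combination_share=self.combination_share,
            k_nearest=self.k_nearest,
            nc_pendant_multiplier=self.nc_pendant_multiplier,
        )


@dataclass
class RunManifest:
    config: dict
    artifacts: dict[str, str]          # relative path -> sha256
    tally: dict
    supernetwork_stats: dict
    stage_seconds: dict[str, float]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage; see the module docstring for the stage order."""
    config.validate()
    outdir = Path(config.outdir)
    (outdir / "cogs").mkdir(parents=True, exist_ok=True)
    (outdir / "trees_true").mkdir(exist_ok=True)
    (outdir / "trees_inferred").mkdir(exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: list[Path] = []
    rng = np.random.default_rng(config.seed)

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    # 1 — taxonomy
    t0 = stage("taxonomy")
    counts = {Category(c): n for c, n in config.n_per_category.items()}
    taxa = simulate_taxonomy(counts, seed=int(rng.integers(2**31)))
    taxonomy_full = TaxonSet(list(taxa) + [_FOCAL_TAXON])
    path = outdir / "taxonomy.tsv"
    taxa.write_tsv(path)
    artifacts.append(path)
    timings["taxonomy"] = time.perf_counter() - t0

    # 2 — planted truth
    t0 = stage("truth")
    truths = plan_cog_truths(config.n_cogs, config.class_fractions,
                             seed=int(rng.integers(2**31)),
                             alleles_per_cog=config.alleles_per_cog)
    path = outdir / "truth.tsv"
    write_truth_tsv(truths, path)
    artifacts.append(path)
    by_cog: dict[str, list] = {}
    for t in truths:
        by_cog.setdefault(t.cog_id, []).append(t)
    timings["truth"] = time.perf_counter() - t0

    # 3 — simulate COGs
    t0 = stage("simulate")
    model = wag()
    alignments = {}
    for cog_id, cog_truths in by_cog.items():
        try:
            aln, true_tree = simulate_cog(
                taxa, cog_truths, n_sites=config.n_sites, model=model,
                gap_fraction=config.gap_fraction, seed=cog_truths[0].seed)
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed on {cog_id}") from exc
        alignments[cog_id] = aln
        p1 = outdir / "cogs" / f"{cog_id}.faa"
        p2 = outdir / "trees_true" / f"{cog_id}.nwk"
        aln.write_fasta(p1)
        true_tree.write_newick(p2)
        artifacts += [p1, p2]
    timings["simulate"] = time.perf_counter() - t0

    # 4 — infer trees (complete deletion + WAG+F + NJ + NNI)
    t0 = stage("infer")
    trees: dict[str, PhyloTree] = {}
    for cog_id, aln in alignments.items():
        try:
            trees[cog_id] = infer_tree(aln, nni_rounds=config.nni_rounds)
        except Exception as exc:
            raise RuntimeError(f"stage infer failed on {cog_id}") from exc
        p = outdir / "trees_inferred" / f"{cog_id}.nwk"
        trees[cog_id].write_newick(p)
        artifacts.append(p)
    timings["infer"] = time.perf_counter() - t0

    # 5 — donor assignment
    t0 = stage("assign")
    params = config.assignment_params()
    calls: list[DonorCall] = []
    for cog_id, aln in alignments.items():
        focal_ids = [t.allele_id for t in by_cog[cog_id]]
        for allele in focal_ids:
            try:
                calls.append(assign_donor(
                    trees[cog_id], taxonomy_full, allele, params,
                    taxon_of=aln.taxon_of, cog_id=cog_id))
            except Exception as exc:
                raise RuntimeError(
                    f"stage assign failed on {cog_id}/{allele}") from exc
    path = outdir / "calls.tsv"
    write_calls_tsv(calls, path)
    artifacts.append(path)
    timings["assign"] = time.perf_counter() - t0

    # 6 — tally
    t0 = stage("tally")
    tally = tally_categories(calls)
    path = outdir / "tally.json"
    tally.to_json(path)
    artifacts.append(path)
    timings["tally"] = time.perf_counter() - t0

    # 7 — pathway annotation (packaged steps mapped onto simulated COG ids)
    t0 = stage("pathway")
    cog_ids = sorted(alignments)
    steps = [
        PathwayStep(s.step_id, s.pathway, s.ec_number,
                    (cog_ids[i % len(cog_ids)],), s.description)
        for i, s in enumerate(default_pathway_steps())
    ]
    annotations = annotate_pathway(steps, calls)
    path = outdir / "pathway_annotation.tsv"
    write_annotations_tsv(annotations, path)
    artifacts.append(path)
    timings["pathway"] = time.perf_counter() - t0

    # 8 — supernetwork over the first k inferred trees; the focal organism
    # is one taxon across trees, so its allele leaf gets a common label
    # (extra paralog leaves are pruned)
    t0 = stage("supernet")
    k = min(config.n_supernetwork_trees, len(cog_ids))
    subset = []
    for c in cog_ids[:k]:
        t = trees[c].copy()
        focal_leaves = sorted(lf for lf in t.leaf_names if lf not in taxa)
        for extra in focal_leaves[1:]:
            t.prune_leaf(extra)
        if focal_leaves:
            t.relabel_leaf(focal_leaves[0], "FOCAL")
        subset.append(t)
    splits = z_closure(trees_to_splits(subset))
    splits = filter_supernetwork(splits, config.min_trees)
    p1 = outdir / "supernetwork.nex"
    p2 = outdir / "supernetwork_stats.json"
    write_splits_nexus(splits, p1)
    stats_payload = stats_json(splits, p2)
    artifacts += [p1, p2]
    timings["supernet"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=asdict(config),
        artifacts={str(p.relative_to(outdir)): _sha256(p)
                   for p in artifacts},
        tally={"counts": tally.counts, "fractions": tally.fractions,
               "n_total": tally.n_total},
        supernetwork_stats=json.loads(stats_payload),
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
    )
    manifest.write(outdir / "manifest.json")
    return manifest
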