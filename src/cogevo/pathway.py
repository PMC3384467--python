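"""Pathway polymorphism annotation.

Joins per-allele donor calls onto enzymatic step definitions (EC number +
the COGs encoding that step) to produce the per-step "n alleles: donor
codes" annotation used to visualise polymorphism along starch/sucrose
metabolism and glycolysis.  A small illustrative step table for those
pathways ships with the package and can be replaced by any TSV with the
same columns.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .donor import DonorCall

__all__ = ["PathwayStep", "StepAnnotation", "annotate_pathway",
           "read_pathway_tsv", "write_annotations_tsv",
           "default_pathway_steps"]

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class PathwayStep:
    step_id: str
    pathway: str  # starch-sucrose | glycolysis-upper | glycolysis-lower
    ec_number: str
    cog_ids: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not _EC_RE.match(self.ec_number):
            raise ValueError(f"invalid EC number {self.ec_number!r}")
        if not self.cog_ids:
            raise ValueError(f"step {self.step_id} lists no COGs")


@dataclass(frozen=True)
class StepAnnotation:
    step_id: str
    n_alleles: int
    codes: tuple[str, ...]

    def render(self) -> str:
        """Figure-style label, e.g. ``"2: B,P"`` or ``"0:"``."""
        return f"{self.n_alleles}: {','.join(self.codes)}" \
            if self.codes else f"{self.n_alleles}:"


def annotate_pathway(steps: list[PathwayStep],
                     calls: list[DonorCall]) -> list[StepAnnotation]:
    """Per-step allele counts and sorted donor codes, in input step order."""
    seen = set()
    for s in steps:
        if s.step_id in seen:
            raise ValueError(f"duplicate step_id {s.step_id!r}")
        seen.add(s.step_id)
    by_cog: dict[str, list[DonorCall]] = {}
    for c in calls:
        by_cog.setdefault(c.cog_id, []).append(c)
    out = []
    for s in steps:
        matched = [c for cid in s.cog_ids for c in by_cog.get(cid, [])]
        if not matched:
            warnings.warn(f"step {s.step_id}: no donor calls for COGs "
                          f"{','.join(s.cog_ids)}", stacklevel=2)
        codes = tuple(sorted(c.code for c in matched))
        out.append(StepAnnotation(s.step_id, len(matched), codes))
    return out


def read_pathway_tsv(path: str | Path) -> list[PathwayStep]:
    steps = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            steps.append(PathwayStep(
                step_id=p[cols["step_id"]],
                pathway=p[cols["pathway"]],
                ec_number=p[cols["ec_number"]],
                cog_ids=tuple(p[cols["cog_ids"]].split(";")),
                description=p[cols["description"]] if "description" in cols
                else "",
            ))
    return steps


def default_pathway_steps() -> list[PathwayStep]:
    """The packaged illustrative starch/sucrose + glycolysis step table."""
    ref = resources.files("cogevo").joinpath("data/pathways.tsv")
    with resources.as_file(ref) as path:
        return read_pathway_tsv(path)


def write_annotations_tsv(annotations: list[StepAnnotation],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("step_id\tn_alleles\tcodes\tlabel\n")
        for a in annotations:
            fh.write(f"{a.step_id}\t{a.n_alleles}\t{','.join(a.codes)}\t"
                     f"{a.render()}\n")
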