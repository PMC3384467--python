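"""Acidic/basic amino-acid composition screen.

Halophilic (and many thermo-tolerant periplasmic) proteins are typically
enriched in acidic residues; the acidic-to-basic ratio is a quick screen
for that character.  Acidic residues are D and E; basic residues default to
the textbook charged set K, R, H, with a switch to restrict to K, R for
sensitivity analysis.  Percentages are taken over all standard residues
after stripping gap/missing symbols; the ratio is reported at one decimal
at the presentation layer only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

ACIDIC_RESIDUES = frozenset("DE")
BASIC_RESIDUES = frozenset("KRH")
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
_STRIP = frozenset("-?*.")


@dataclass(frozen=True)
class CompositionReport:
    sequence_id: str
    n_residues: int
    acidic_percent: float
    basic_percent: float
    ratio: float | None  # None when basic_percent == 0 (undefined)

    @property
    def ratio_undefined(self) -> bool:
        return self.ratio is None

    @property
    def ratio_rounded(self) -> float | None:
        return None if self.ratio is None else round(self.ratio, 1)


def acid_base_ratio(sequence: str, sequence_id: str = "",
                    basic_residues: frozenset[str] = BASIC_RESIDUES
                    ) -> CompositionReport:
    """Acidic and basic residue percentages and their ratio for one protein."""
    cleaned = [c for c in sequence.upper() if c not in _STRIP]
    residues = [c for c in cleaned if c in STANDARD_RESIDUES]
    if not cleaned:
        raise ValueError("sequence empty after removing gap/missing symbols")
    if not residues:
        raise ValueError("sequence contains no standard residues")
    n = len(residues)
    acidic = sum(1 for c in residues if c in ACIDIC_RESIDUES)
    basic = sum(1 for c in residues if c in basic_residues)
    acidic_pct = 100.0 * acidic / n
    basic_pct = 100.0 * basic / n
    ratio = acidic_pct / basic_pct if basic > 0 else None
    return CompositionReport(sequence_id, n, acidic_pct, basic_pct, ratio)


def screen_fasta(path: str | Path,
                 basic_residues: frozenset[str] = BASIC_RESIDUES
                 ) -> list[CompositionReport]:
    """Composition report for every sequence in a protein FASTA file."""
    return [acid_base_ratio(str(rec.seq), rec.id, basic_residues)
            for rec in SeqIO.parse(str(path), "fasta")]


def write_reports_csv(reports: list[CompositionReport],
                      path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "n_residues", "acidic_percent", "basic_percent",
                    "ratio"])
        for r in reports:
            w.writerow([r.sequence_id, r.n_residues,
                        f"{r.acidic_percent:.4f}", f"{r.basic_percent:.4f}",
                        "NA" if r.ratio is None else f"{r.ratio_rounded:.1f}"])
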