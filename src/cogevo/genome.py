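"""Genome summary statistics: GC content and gene/intergenic occupancy.

Coordinates are 1-based inclusive throughout; conversion to half-open
happens only at format boundaries (GFF3 is itself 1-based inclusive, so no
conversion is needed there).  Overlapping gene intervals are merged before
measuring occupied length, because "length occupied by genes" is a coverage
notion: double counting could exceed the chromosome.  Gene plus intergenic
length always equals the total exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "GenomeStats",
    "gc_content",
    "occupancy",
    "round_percent",
]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid gene interval {self.gene_id}: "
                             f"{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class GenomeAnnotation:
    contig_id: str
    contig_length: int
    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in annotation")
        for g in self.genes:
            if g.end > self.contig_length:
                raise ValueError(
                    f"gene {g.gene_id} extends past contig end "
                    f"({g.end} > {self.contig_length})")

    # -- IO ---------------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tstart\tend\tstrand\n")
            for g in self.genes:
                fh.write(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, contig_id: str,
                 contig_length: int) -> "GenomeAnnotation":
        genes = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                p = line.rstrip("\n").split("\t")
                genes.append(Gene(p[cols["gene_id"]], int(p[cols["start"]]),
                                  int(p[cols["end"]]), p[cols["strand"]]))
        return cls(contig_id, contig_length, genes)

    @classmethod
    def read_gff3(cls, path: str | Path, contig_length: int,
                  feature_types: tuple[str, ...] = ("gene", "CDS")
                  ) -> "GenomeAnnotation":
        """Minimal GFF3 reader: seqid, type, start, end, strand columns."""
        genes = []
        contig_id = ""
        n = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                p = line.rstrip("\n").split("\t")
                if len(p) < 8 or p[2] not in feature_types:
                    continue
                contig_id = contig_id or p[0]
                n += 1
                genes.append(Gene(f"g{n:05d}", int(p[3]), int(p[4]),
                                  p[6] if p[6] in "+-" else "+"))
        return cls(contig_id or "contig1", contig_length, genes)


@dataclass
class GenomeStats:
    total_bases: int
    gc_percent: float
    n_genes: int
    gene_length: int
    gene_gc_percent: float
    gene_fraction_percent: float
    intergenic_length: int
    intergenic_gc_percent: float
    intergenic_fraction_percent: float

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            fields = list(self.__dataclass_fields__)
            w.writerow(fields)
            w.writerow([
                round_percent(getattr(self, f), 2)
                if f.endswith("percent") else getattr(self, f)
                for f in fields
            ])


def round_percent(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as in conventional table formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_content(sequence: str) -> float:
    """Percent G+C over unambiguous bases; N is excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in DNA sequence: {sorted(bad)}")
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / denom


def _merged_intervals(genes: list[Gene]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, strand-ignored."""
    if not genes:
        return []
    ivals = sorted((g.start, g.end) for g in genes)
    merged = [ivals[0]]
    for s, e in ivals[1:]:
        ps, pe = merged[-1]
        if s <= pe + 1:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def occupancy(annotation: GenomeAnnotation, sequence: str) -> GenomeStats:
    """Gene/intergenic occupancy and per-region GC of one contig."""
    if len(sequence) != annotation.contig_length:
        raise ValueError("sequence length disagrees with annotation")
    total = annotation.contig_length
    merged = _merged_intervals(annotation.genes)
    gene_length = sum(e - s + 1 for s, e in merged)
    intergenic_length = total - gene_length

    import numpy as np
    gene_seq = "".join(sequence[s - 1:e] for s, e in merged)
    mask = np.zeros(total, dtype=bool)
    for s, e in merged:
        mask[s - 1:e] = True
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    intergenic_seq = arr[~mask].tobytes().decode()

    return GenomeStats(
        total_bases=total,
        gc_percent=gc_content(sequence),
        n_genes=len(annotation.genes),
        gene_length=gene_length,
        gene_gc_percent=gc_content(gene_seq) if gene_seq else 0.0,
        gene_fraction_percent=100.0 * gene_length / total,
        intergenic_length=intergenic_length,
        intergenic_gc_percent=(gc_content(intergenic_seq)
                               if intergenic_seq else 0.0),
        intergenic_fraction_percent=100.0 * intergenic_length / total,
    )


def read_fasta_sequence(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as (id, sequence)."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()
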