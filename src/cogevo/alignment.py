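"""Aligned protein sequences for one cluster of orthologous groups (COG)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .wag_data import AA_INDEX, AMINO_ACIDS

#: Symbols treated as missing data (gap and unknown).
MISSING_SYMBOLS = frozenset("-?")

#: Integer code for a missing cell in encoded alignments.
MISSING_CODE = 20


@dataclass
class CogAlignment:
    """One COG's aligned members: reference taxa plus >= 1 focal alleles.

    ``taxon_of`` maps each member sequence id to the taxon it came from
    (several focal alleles may map to the same focal organism).
    """

    cog_id: str
    ids: list[str]
    seqs: list[str]
    taxon_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in {self.cog_id}")
        alphabet = set(AMINO_ACIDS) | MISSING_SYMBOLS
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - alphabet
            if bad:
                raise ValueError(
                    f"invalid residue(s) {sorted(bad)} in {sid} of {self.cog_id}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def encoded(self) -> np.ndarray:
        """(n_members, n_sites) int8 matrix; missing cells = MISSING_CODE."""
        table = np.full(128, MISSING_CODE, dtype=np.int8)
        for a, i in AA_INDEX.items():
            table[ord(a)] = i
        return np.vstack([
            table[np.frombuffer(s.encode(), dtype=np.uint8)] for s in self.seqs
        ]) if self.seqs else np.empty((0, 0), dtype=np.int8)

    # -- IO ---------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(s), id=i, description="")
                   for i, s in zip(self.ids, self.seqs)]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path, cog_id: str | None = None,
                   taxon_of: dict[str, str] | None = None) -> "CogAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if cog_id is None:
            cog_id = Path(path).stem
        return cls(
            cog_id=cog_id,
            ids=[r.id for r in records],
            seqs=[str(r.seq).upper() for r in records],
            taxon_of=taxon_of or {r.id: r.id for r in records},
        )
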