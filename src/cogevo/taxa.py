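"""Reference taxa and their clade categories.

Donor attribution classifies the neighbours of a focal allele by clade
category: Proteobacteria (P), other bacteria (B), thermophilic archaea (T),
halophilic archaea (HA) and other archaea (A).  The focal organism's own
alleles carry the special category FOCAL and never vote as neighbours.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class Category(str, enum.Enum):
    PROTEO = "PROTEO"
    OTHER_BACT = "OTHER_BACT"
    THERMO_ARCH = "THERMO_ARCH"
    HALO_ARCH = "HALO_ARCH"
    OTHER_ARCH = "OTHER_ARCH"
    FOCAL = "FOCAL"

    @property
    def domain(self) -> str:
        if self in (Category.PROTEO, Category.OTHER_BACT, Category.FOCAL):
            return "Bacteria"
        return "Archaea"

    @property
    def code(self) -> str:
        """Donor-category code used in figure-style annotations."""
        return _CODES[self]


_CODES = {
    Category.PROTEO: "P",
    Category.OTHER_BACT: "B",
    Category.THERMO_ARCH: "T",
    Category.HALO_ARCH: "HA",
    Category.OTHER_ARCH: "A",
    Category.FOCAL: "FOCAL",
}

#: Reference categories (everything except FOCAL).
REFERENCE_CATEGORIES = (
    Category.PROTEO,
    Category.OTHER_BACT,
    Category.THERMO_ARCH,
    Category.HALO_ARCH,
    Category.OTHER_ARCH,
)

CODE_TO_CATEGORY = {c.code: c for c in REFERENCE_CATEGORIES}


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    name: str
    category: Category

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")

    @property
    def domain(self) -> str:
        return self.category.domain


class TaxonSet:
    """Ordered collection of uniquely identified taxa."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: list[TaxonRecord] = list(records)
        self._by_id = {r.taxon_id: r for r in self._records}
        if len(self._by_id) != len(self._records):
            raise ValueError("duplicate taxon_id in TaxonSet")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self._records)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._by_id

    def __getitem__(self, taxon_id: str) -> TaxonRecord:
        return self._by_id[taxon_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonSet) and self._records == other._records

    def category_of(self, taxon_id: str) -> Category:
        return self._by_id[taxon_id].category

    def ids(self, category: Category | None = None) -> list[str]:
        if category is None:
            return [r.taxon_id for r in self._records]
        return [r.taxon_id for r in self._records if r.category is category]

    def histogram(self) -> dict[Category, int]:
        h: dict[Category, int] = {}
        for r in self._records:
            h[r.category] = h.get(r.category, 0) + 1
        return h

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tdomain\tcategory\n")
            for r in self._records:
                fh.write(f"{r.taxon_id}\t{r.domain}\t{r.category.value}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonSet":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                records.append(TaxonRecord(
                    taxon_id=parts[cols["taxon_id"]],
                    name=parts[cols.get("name", cols["taxon_id"])],
                    category=Category(parts[cols["category"]]),
                ))
        return cls(records)
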