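"""Leaf-label → species-code resolution.

A :class:`SpeciesMap` combines an explicit lookup table (two-column TSV,
``#`` comments allowed) with a naming-convention fallback that takes the
token after the last delimiter in the label (``ENSP00000123_HSA`` → ``HSA``).
The table always wins when both apply.  It also carries the study design:
which species are query genomes (the proteomes being classified) and which
are the references to classify against (human then zebrafish by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import SpeciesResolutionError

DEFAULT_REFERENCE_SPECIES = ("HSA", "DRE")
DEFAULT_QUERY_SPECIES = ("MZE", "PNY", "ABU", "NBR")


@dataclass(frozen=True)
class SpeciesMap:
    query_species: tuple[str, ...] = DEFAULT_QUERY_SPECIES
    reference_species: tuple[str, ...] = DEFAULT_REFERENCE_SPECIES
    table: Mapping[str, str] | None = None
    delimiter: str | None = "_"  # None disables the pattern fallback

    def __post_init__(self):
        object.__setattr__(self, "query_species", tuple(self.query_species))
        object.__setattr__(self, "reference_species", tuple(self.reference_species))
        overlap = set(self.query_species) & set(self.reference_species)
        if overlap:
            raise SpeciesResolutionError(
                f"query and reference species must be disjoint; both contain {sorted(overlap)}"
            )

    @property
    def mode(self) -> str:
        return "table" if self.table is not None and self.delimiter is None else "pattern"

    def resolve(self, label: str) -> str:
        """Species code for a leaf label; table mode overrides pattern mode."""
        if not label:
            raise SpeciesResolutionError("cannot resolve an empty leaf label")
        if self.table is not None and label in self.table:
            return self.table[label]
        if self.delimiter is not None and self.delimiter in label:
            return label.rsplit(self.delimiter, 1)[1]
        raise SpeciesResolutionError(
            f"leaf label {label!r} not in the species table and does not match the pattern rule"
        )

    def is_reference(self, label: str) -> bool:
        return self.resolve(label) in self.reference_species

    def is_query(self, label: str) -> bool:
        return self.resolve(label) in self.query_species

    def with_table(self, table: Mapping[str, str]) -> "SpeciesMap":
        merged = dict(self.table or {})
        merged.update(table)
        return SpeciesMap(self.query_species, self.reference_species, merged, self.delimiter)

    @classmethod
    def from_table_file(
        cls,
        path,
        query_species=DEFAULT_QUERY_SPECIES,
        reference_species=DEFAULT_REFERENCE_SPECIES,
        delimiter: str | None = "_",
    ) -> "SpeciesMap":
        """Load a two-column TSV (leaf label, species code); '#' starts a comment."""
        table: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise SpeciesResolutionError(
                    f"{path}:{lineno}: expected two columns (leaf label, species code)"
                )
            table[parts[0]] = parts[1]
        return cls(tuple(query_species), tuple(reference_species), table, delimiter)
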