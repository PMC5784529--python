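"""Reduce an annotated proteome to one representative protein per gene, and
load ID-mapping tables (protein/gene ID → display symbol).

The representative is the longest isoform (length measured on the amino-acid
sequence, excluding a trailing stop ``*``); equal lengths are broken by the
lexicographically smallest protein ID.  Gene–transcript–protein linkage
follows GFF3 ``Parent``/``ID`` chains by default, with the feature types and
attribute keys configurable because annotation conventions differ between
assemblies.  All readers tolerate gzip.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO

from .errors import IngestError

logger = logging.getLogger(__name__)

__all__ = ["GeneRecord", "IdMap", "IngestSummary", "select_longest_isoforms", "load_id_map"]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chosen_protein_id: str
    protein_length: int  # amino acids, trailing '*' excluded
    n_isoforms: int


@dataclass
class IngestSummary:
    n_genes: int = 0
    n_proteins_seen: int = 0
    missing_in_fasta: list[str] = field(default_factory=list)
    unannotated_sequences: list[str] = field(default_factory=list)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, encoding="utf-8")


def _read_fasta(path, id_trim: str | None) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            pid = rec.id
            if id_trim and id_trim in pid:
                pid = pid.split(id_trim, 1)[0]
            seqs[pid] = str(rec.seq)
    return seqs


def select_longest_isoforms(
    annotation,
    proteins,
    feature_types: Iterable[str] = ("mRNA", "transcript"),
    gene_attribute: str = "Parent",
    protein_attribute: str | None = "protein_id",
    id_trim: str | None = None,
) -> tuple[list[GeneRecord], dict[str, str], IngestSummary]:
    """One representative (longest) protein per gene.

    Parameters
    ----------
    annotation
        GFF3 path (optionally gzipped).  Features of ``feature_types`` are
        linked to their gene via ``gene_attribute`` (default the ``Parent``
        chain) and to their protein via ``protein_attribute`` when present,
        else the feature ``ID``.
    proteins
        Protein FASTA path; IDs are matched to annotation protein IDs after
        stripping everything from ``id_trim`` onward (e.g. ``"."`` to drop
        version suffixes), when given.

    Returns
    -------
    (records, sequences, summary)
        One :class:`GeneRecord` per gene with a sequence-resolvable isoform,
        sorted by gene ID; the representative sequences keyed by protein ID;
        and a summary counting proteins annotated but absent from the FASTA
        (warned, excluded) and sequences with no annotation (excluded).
    """
    seqs = _read_fasta(proteins, id_trim)
    if not seqs:
        raise IngestError(f"no sequences found in {proteins}")
    db = gffutils.create_db(
        str(annotation), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", from_string=False,
    )
    summary = IngestSummary()
    by_gene: dict[str, list[tuple[str, int]]] = {}
    seen_pids: set[str] = set()
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            if gene_attribute == "Parent":
                parents = feat.attributes.get("Parent", [])
                gene = parents[0] if parents else feat.id
            else:
                vals = feat.attributes.get(gene_attribute, [])
                gene = vals[0] if vals else feat.id
            pid = feat.id
            if protein_attribute and protein_attribute in feat.attributes:
                pid = feat.attributes[protein_attribute][0]
            seen_pids.add(pid)
            summary.n_proteins_seen += 1
            if pid not in seqs:
                summary.missing_in_fasta.append(pid)
                logger.warning("protein %s annotated for gene %s but absent from FASTA", pid, gene)
                continue
            length = len(seqs[pid].rstrip("*"))
            by_gene.setdefault(gene, []).append((pid, length))
    summary.unannotated_sequences = sorted(set(seqs) - seen_pids)
    records: list[GeneRecord] = []
    representative: dict[str, str] = {}
    for gene in sorted(by_gene):
        isoforms = by_gene[gene]
        # longest wins; length ties go to the lexicographically smallest ID
        pid, length = min(isoforms, key=lambda it: (-it[1], it[0]))
        records.append(
            GeneRecord(gene_id=gene, chosen_protein_id=pid,
                       protein_length=length, n_isoforms=len(isoforms))
        )
        representative[pid] = seqs[pid]
    summary.n_genes = len(records)
    if not records:
        raise IngestError(
            f"no genes could be linked between {annotation} and {proteins}; "
            f"check feature_types/attribute settings"
        )
    return records, representative, summary


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(sequences):
            fh.write(f">{pid}\n{sequences[pid]}\n")


class IdMap:
    """Protein/gene ID → display symbol with pass-through for unmapped IDs."""

    def __init__(self, table: dict[str, str], conflicts: list[tuple[str, str, str]] | None = None):
        self._table = table
        self.conflicts = conflicts or []

    def lookup(self, source_id: str) -> tuple[str, bool]:
        """Return ``(symbol, mapped)``; unmapped IDs pass through unchanged."""
        if source_id in self._table:
            return self._table[source_id], True
        return source_id, False

    def __len__(self):
        return len(self._table)

    def __contains__(self, source_id):
        return source_id in self._table


def load_id_map(path) -> IdMap:
    """Load a ≥2-column TSV of (source ID, symbol).

    Duplicate source IDs keep the first symbol; the conflict is logged and
    recorded on the returned map.  An empty file is an error.
    """
    table: dict[str, str] = {}
    conflicts: list[tuple[str, str, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise IngestError(f"{path}:{lineno}: expected at least two columns")
            src, symbol = parts[0], parts[1]
            if src in table:
                if table[src] != symbol:
                    conflicts.append((src, table[src], symbol))
                    logger.warning(
                        "duplicate ID %s: keeping %s, ignoring %s", src, table[src], symbol
                    )
                continue
            table[src] = symbol
    if not table:
        raise IngestError(f"ID map {path} contains no mappings")
    return IdMap(table, conflicts)
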