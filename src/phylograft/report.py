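"""Assemble per-species homology tables and run the whole pipeline.

The report is one row per query gene: its family, its closest human and
zebrafish proteins with relationship and multiplicity, the median copy
number over the query genomes, and the chimera flag — the tabular
deliverable a genome-wide screen produces.  Output is TSV (diffable and
losslessly convertible), sorted by gene ID, and a pure function of the
inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import PipelineError
from .families import FamilyAssignment, assign_families, parse_hit_table, write_assignment_table
from .homology import HomologyCall, batch_call_genes
from .ingest import GeneRecord, IdMap, load_id_map, select_longest_isoforms, write_fasta
from .species import SpeciesMap
from .tree import read_newick_file

logger = logging.getLogger(__name__)

__all__ = ["build_report", "summarize", "run_pipeline", "PipelineResult"]

#: Friendly column prefixes for the usual reference species codes.
_REF_NAMES = {"HSA": "human", "DRE": "zebrafish", "MMU": "mouse"}


def _ref_prefix(code: str) -> str:
    return _REF_NAMES.get(code, code.lower())


def build_report(
    gene_records: list[GeneRecord],
    assignments: Mapping[str, FamilyAssignment],
    calls_by_gene: Mapping[str, list[HomologyCall]],
    id_map: IdMap | None = None,
    smap: SpeciesMap | None = None,
) -> pd.DataFrame:
    """One row per query gene, sorted by gene ID.

    Genes without a family assignment appear with family ``NA`` and
    relationship ``no_family_hit``; genes whose family tree was unusable
    carry ``no_tree``.  Reference protein IDs are translated to display
    symbols through ``id_map`` (unmapped IDs pass through).
    """
    refs = smap.reference_species if smap is not None else ("HSA", "DRE")
    rows = []
    for rec in sorted(gene_records, key=lambda r: r.gene_id):
        a = assignments.get(rec.chosen_protein_id)
        if a is None:
            raise PipelineError(
                f"integrity error: gene {rec.gene_id} (protein {rec.chosen_protein_id}) "
                f"has no family assignment record"
            )
        row: dict[str, object] = {
            "gene_id": rec.gene_id,
            "protein_id": rec.chosen_protein_id,
            "family_id": a.best_family_id if a.assigned else "NA",
            "chimera_flag": int(a.chimera_flag),
        }
        calls = calls_by_gene.get(rec.gene_id)
        for ref in refs:
            prefix = _ref_prefix(ref)
            call = None
            if calls:
                call = next((c for c in calls if c.reference_species == ref), None)
            if not a.assigned:
                rel = "no_family_hit"
            elif call is None:
                rel = "no_tree"
            else:
                rel = call.relationship
            row[f"{prefix}_relationship"] = rel
            protein = call.closest_reference_protein if call else None
            symbol = None
            if protein is not None:
                symbol = id_map.lookup(protein)[0] if id_map is not None else protein
            row[f"closest_{prefix}_protein"] = protein or "NA"
            row[f"{prefix}_symbol"] = symbol or "NA"
            row[f"{prefix}_distance"] = (
                round(call.distance, 9) if call and call.distance is not None else "NA"
            )
            row[f"{prefix}_multiplicity"] = (call.multiplicity if call else None) or "NA"
            row[f"{prefix}_x"] = call.x_value if call and call.x_value is not None else "NA"
            if ref == refs[0]:
                row["median_query_copies"] = (
                    call.median_query_copies
                    if call and call.median_query_copies is not None
                    else "NA"
                )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame, reference: str = "HSA") -> dict[str, object]:
    """Relationship-category counts (first reference species) plus the
    fraction of genes with a family hit; categories sum to the gene total."""
    prefix = _ref_prefix(reference)
    rel = report[f"{prefix}_relationship"]
    mult = report[f"{prefix}_multiplicity"]
    n = len(report)
    counts = {
        "one-to-one ortholog": int(((rel == "ortholog") & (mult == "one-to-one")).sum()),
        "one-to-two ortholog": int(((rel == "ortholog") & (mult == "one-to-two")).sum()),
        "one-to-X (X>2) ortholog": int(
            (
                (rel == "ortholog")
                & mult.str.startswith("one-to-")
                & ~mult.isin(["one-to-one", "one-to-two"])
            ).sum()
        ),
        "many-to-X ortholog (extension)": int(
            ((rel == "ortholog") & mult.str.startswith("many-to-")).sum()
        ),
        "paralog": int((rel == "paralog").sum()),
        "no_homolog": int((rel == "no_homolog").sum()),
        "no_family_hit": int((rel == "no_family_hit").sum()),
        "no_tree": int((rel == "no_tree").sum()),
    }
    assert sum(counts.values()) == n, "summary categories must partition the genes"
    with_hit = int((report["family_id"] != "NA").sum())
    return {
        "n_genes": n,
        "counts": counts,
        "fraction_with_family_hit": (with_hit / n) if n else 0.0,
    }


@dataclass
class PipelineResult:
    report_path: Path
    summary_path: Path
    assignment_path: Path
    report: pd.DataFrame
    summary: dict[str, object]
    skipped_trees: list[tuple[str, str]] = field(default_factory=list)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _species_map_from_config(cfg: dict) -> SpeciesMap:
    query = tuple(cfg.get("query_species", ("MZE", "PNY", "ABU", "NBR")))
    refs = tuple(cfg.get("reference_species", ("HSA", "DRE")))
    delimiter = cfg.get("delimiter", "_")
    smap = SpeciesMap(query, refs, None, delimiter)
    if cfg.get("species_map"):
        smap = SpeciesMap.from_table_file(
            cfg["species_map"], query_species=query,
            reference_species=refs, delimiter=delimiter,
        )
    return smap


def run_pipeline(config, out_dir, seed: int = 0) -> PipelineResult:
    """Ingest → family assignment → classification → report.

    ``config`` is a mapping or a YAML file naming the inputs (``proteins``,
    ``annotation``, ``hits``, ``trees_dir``, optional ``id_map``,
    ``species_map``, species lists, ``delimiter``).  External grafting is
    assumed pre-computed: the family trees under ``trees_dir`` must already
    contain the query protein leaves; genes whose tree is missing or lacks
    their leaf are reported as ``no_tree``.  Any stage failure aborts with
    the stage name; partial outputs are removed.  ``seed`` is accepted for
    interface symmetry — every stage is deterministic.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "configuration"
    try:
        smap = _species_map_from_config(cfg)
        focal = cfg.get("focal_species", smap.query_species[0])

        stage = "ingest"
        records, sequences, ing_summary = select_longest_isoforms(
            cfg["annotation"], cfg["proteins"],
            feature_types=tuple(cfg.get("feature_types", ("mRNA", "transcript"))),
            gene_attribute=cfg.get("gene_attribute", "Parent"),
            protein_attribute=cfg.get("protein_attribute", "protein_id"),
            id_trim=cfg.get("id_trim"),
        )
        write_fasta(sequences, out / "representative.fasta")
        logger.info("ingest: %d genes, %d representative proteins",
                    len(records), len(sequences))

        stage = "family assignment"
        hits = parse_hit_table(cfg["hits"])
        assignments = assign_families(
            hits, proteins=sequences.keys(),
            mode=cfg.get("scoring_mode", "sum"),
            max_overlap_frac=float(cfg.get("max_overlap_frac", 0.1)),
            min_region_len=int(cfg.get("min_region_len", 50)),
        )
        write_assignment_table(assignments, out / "assignments.tsv")
        logger.info("assignment: %d/%d proteins assigned",
                    sum(a.assigned for a in assignments.values()), len(assignments))

        stage = "classification"
        trees_dir = Path(cfg["trees_dir"])
        by_family: dict[str, list[GeneRecord]] = {}
        for rec in records:
            a = assignments[rec.chosen_protein_id]
            if a.assigned:
                by_family.setdefault(a.best_family_id, []).append(rec)
        calls_by_gene: dict[str, list] = {}
        skipped: list[tuple[str, str]] = []
        for fam in sorted(by_family):
            tree_path = trees_dir / f"{fam}.nwk"
            if not tree_path.exists():
                skipped.append((fam, "tree file missing"))
                continue
            tree = read_newick_file(tree_path)[0]
            present = [r for r in by_family[fam] if r.chosen_protein_id in tree]
            absent = [r for r in by_family[fam] if r.chosen_protein_id not in tree]
            if absent:
                skipped.append(
                    (fam, f"{len(absent)} assigned proteins absent from tree (graft not run?)")
                )
            if present:
                calls = batch_call_genes(
                    tree, [r.chosen_protein_id for r in present], smap, family=fam,
                    count_absent_species=bool(cfg.get("count_absent_species", True)),
                )
                for r in present:
                    calls_by_gene[r.gene_id] = [
                        dataclasses.replace(c, query_gene=r.gene_id)
                        for c in calls[r.chosen_protein_id]
                    ]
        logger.info("classification: %d genes called, %d families skipped",
                    len(calls_by_gene), len(skipped))

        stage = "report"
        id_map = load_id_map(cfg["id_map"]) if cfg.get("id_map") else None
        report = build_report(records, assignments, calls_by_gene, id_map, smap)
        summary = summarize(report, smap.reference_species[0])
        report_path = out / f"report_{focal}.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        summary_path = out / "summary.txt"
        with open(summary_path, "w", encoding="utf-8") as fh:
            fh.write(f"genes\t{summary['n_genes']}\n")
            for cat, cnt in summary["counts"].items():
                fh.write(f"{cat}\t{cnt}\n")
            fh.write(f"fraction_with_family_hit\t{summary['fraction_with_family_hit']:.4f}\n")
        return PipelineResult(
            report_path=report_path, summary_path=summary_path,
            assignment_path=out / "assignments.tsv",
            report=report, summary=summary, skipped_trees=skipped,
        )
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for name in ("representative.fasta", "assignments.tsv", "summary.txt"):
                (out / name).unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed at stage '{stage}': {exc}") from exc
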