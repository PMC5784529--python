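"""Turn profile-HMM hit tables into one best family per protein, flag
chimeric annotations, and prepare grafting bundles for external tools.

The hit table is the standard per-domain tabular output of a profile search
(domtblout column order: target/HMM name first, query sequence fourth,
per-domain score and independent E-value in columns 14 and 13, alignment
coordinates on the query in columns 18–19).  A protein's best family is the
one with the highest summed domain bit score (``mode="max"`` switches to
best single domain); ties go to the lower combined E-value, then the
lexicographically smallest family ID.

A *chimeric* annotation — one predicted protein fusing two adjacent genes —
shows up as the two top families hitting essentially disjoint regions of
the protein.  Flagged assignments carry both families and regions so the
call can be re-examined manually.

Alignment and tree re-estimation are performed by external programs (e.g.
``mafft --add`` and RAxML); this module only prepares their per-family
input bundles and leaves a manifest behind, deterministically.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import HitTableError, PipelineError

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyHit",
    "ChimeraDetail",
    "FamilyAssignment",
    "parse_hit_table",
    "assign_best_family",
    "flag_chimeric",
    "assign_families",
    "prepare_graft_bundle",
]


@dataclass(frozen=True)
class FamilyHit:
    protein_id: str
    family_id: str
    bit_score: float
    e_value: float
    query_start: int  # 1-based inclusive, amino acids
    query_end: int

    def __post_init__(self):
        if self.query_start > self.query_end:
            raise HitTableError(
                f"hit on {self.protein_id}: start {self.query_start} > end {self.query_end}"
            )
        if self.e_value < 0:
            raise HitTableError(f"hit on {self.protein_id}: negative e-value")


@dataclass(frozen=True)
class ChimeraDetail:
    family_a: str
    region_a: tuple[int, int]
    family_b: str
    region_b: tuple[int, int]


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    best_family_id: str | None  # None = unassigned (no hits)
    best_bit_score: float | None
    chimera_flag: bool = False
    chimera_detail: ChimeraDetail | None = None

    @property
    def assigned(self) -> bool:
        return self.best_family_id is not None


def parse_hit_table(path, strict: bool = False) -> list[FamilyHit]:
    """Parse a per-domain tabular profile-search file into FamilyHits.

    Comment lines start with ``#``.  Malformed rows are skipped with their
    line numbers logged (``strict=True`` raises instead); a file with no
    parseable rows is always an error.
    """
    hits: list[FamilyHit] = []
    bad: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) < 22:
                    raise ValueError("fewer than 22 columns")
                hit = FamilyHit(
                    protein_id=fields[3],
                    family_id=fields[0],
                    bit_score=float(fields[13]),
                    e_value=float(fields[12]),
                    query_start=int(fields[17]),
                    query_end=int(fields[18]),
                )
            except (ValueError, HitTableError) as exc:
                if strict:
                    raise HitTableError(f"{path}:{lineno}: malformed row ({exc})") from exc
                bad.append(lineno)
                continue
            hits.append(hit)
    if bad:
        logger.warning("%s: skipped %d malformed rows (lines %s)", path, len(bad), bad)
    if not hits:
        raise HitTableError(f"no parseable rows in {path}")
    return hits


def _family_scores(hits: Sequence[FamilyHit], mode: str) -> dict[str, tuple[float, float]]:
    """Per-family (score, combined e-value) for one protein's hits."""
    scores: dict[str, float] = {}
    evalues: dict[str, float] = {}
    for h in hits:
        if mode == "sum":
            scores[h.family_id] = scores.get(h.family_id, 0.0) + h.bit_score
        elif mode == "max":
            scores[h.family_id] = max(scores.get(h.family_id, float("-inf")), h.bit_score)
        else:
            raise ValueError(f"unknown scoring mode {mode!r}")
        evalues[h.family_id] = evalues.get(h.family_id, 0.0) + h.e_value
    return {f: (scores[f], evalues[f]) for f in scores}


def assign_best_family(hits: Sequence[FamilyHit], mode: str = "sum") -> FamilyAssignment:
    """Best family for one protein's hits (empty hits ⇒ unassigned)."""
    if not hits:
        raise ValueError("assign_best_family needs the protein's hits; use assign_families "
                         "for proteins that may have none")
    protein = hits[0].protein_id
    if any(h.protein_id != protein for h in hits):
        raise ValueError("assign_best_family expects hits for a single protein")
    fam_scores = _family_scores(hits, mode)
    # highest score, then lowest combined e-value, then lexicographic family ID
    best = min(fam_scores, key=lambda f: (-fam_scores[f][0], fam_scores[f][1], f))
    return FamilyAssignment(protein_id=protein, best_family_id=best,
                            best_bit_score=fam_scores[best][0])


def flag_chimeric(
    hits: Sequence[FamilyHit],
    max_overlap_frac: float = 0.1,
    min_region_len: int = 50,
    mode: str = "sum",
) -> tuple[bool, ChimeraDetail | None]:
    """Detect the fused-two-genes signature on one protein's hits.

    The two top-scoring families' hit regions (envelope over their domains)
    must each span at least ``min_region_len`` residues and overlap by at
    most ``max_overlap_frac`` of the shorter region.  Two families hitting
    the same stretch are competing homology, not fusion, and are not
    flagged; neither is a single-family protein.
    """
    fam_scores = _family_scores(hits, mode)
    if len(fam_scores) < 2:
        return False, None
    ranked = sorted(fam_scores, key=lambda f: (-fam_scores[f][0], fam_scores[f][1], f))
    fa, fb = ranked[0], ranked[1]
    regions = {}
    for fam in (fa, fb):
        fam_hits = [h for h in hits if h.family_id == fam]
        regions[fam] = (min(h.query_start for h in fam_hits),
                        max(h.query_end for h in fam_hits))
    (sa, ea), (sb, eb) = regions[fa], regions[fb]
    len_a, len_b = ea - sa + 1, eb - sb + 1
    if min(len_a, len_b) < min_region_len:
        return False, None
    overlap = max(0, min(ea, eb) - max(sa, sb) + 1)
    if overlap <= max_overlap_frac * min(len_a, len_b):
        return True, ChimeraDetail(family_a=fa, region_a=regions[fa],
                                   family_b=fb, region_b=regions[fb])
    return False, None


def assign_families(
    hits: Iterable[FamilyHit],
    proteins: Iterable[str] | None = None,
    mode: str = "sum",
    max_overlap_frac: float = 0.1,
    min_region_len: int = 50,
) -> dict[str, FamilyAssignment]:
    """Assignments for every protein, unassigned records included.

    ``proteins`` names the full protein universe so that proteins with no
    hits appear as unassigned; omitted, only proteins with hits are
    returned.  Row order of the hit table never affects the result.
    """
    grouped: dict[str, list[FamilyHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    out: dict[str, FamilyAssignment] = {}
    universe = set(proteins) if proteins is not None else set(grouped)
    for pid in sorted(universe | set(grouped)):
        phits = sorted(
            grouped.get(pid, []),
            key=lambda h: (h.family_id, h.query_start, h.query_end, -h.bit_score),
        )
        if not phits:
            out[pid] = FamilyAssignment(protein_id=pid, best_family_id=None,
                                        best_bit_score=None)
            continue
        base = assign_best_family(phits, mode=mode)
        flag, detail = flag_chimeric(phits, max_overlap_frac=max_overlap_frac,
                                     min_region_len=min_region_len, mode=mode)
        out[pid] = FamilyAssignment(
            protein_id=pid, best_family_id=base.best_family_id,
            best_bit_score=base.best_bit_score, chimera_flag=flag, chimera_detail=detail,
        )
    return out


def write_assignment_table(assignments: Mapping[str, FamilyAssignment], path) -> None:
    """TSV: protein_id, family_id, bit_score, e_value placeholder, chimera columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tfamily_id\tbit_score\tchimera_flag\tchimera_detail\n")
        for pid in sorted(assignments):
            a = assignments[pid]
            fam = a.best_family_id if a.assigned else "NA"
            score = f"{a.best_bit_score:.1f}" if a.best_bit_score is not None else "NA"
            detail = ""
            if a.chimera_detail:
                d = a.chimera_detail
                detail = (f"{d.family_a}:{d.region_a[0]}-{d.region_a[1]};"
                          f"{d.family_b}:{d.region_b[0]}-{d.region_b[1]}")
            fh.write(f"{pid}\t{fam}\t{score}\t{int(a.chimera_flag)}\t{detail}\n")


@dataclass
class BundleResult:
    bundles: list[str]  # family IDs with a bundle written
    skipped: list[tuple[str, str]]  # (family ID, reason)


def prepare_graft_bundle(
    assignments: Mapping[str, FamilyAssignment],
    sequences: Mapping[str, str],
    out_dir,
    alignment_dir=None,
    tree_dir=None,
) -> BundleResult:
    """Write one grafting job bundle per family with newly assigned proteins.

    Each bundle directory holds ``new_seqs.fasta`` (the proteins to graft,
    sorted), copies of the family's reference alignment and Newick tree when
    the source directories are given, and a ``manifest.tsv``.  Re-running on
    unchanged inputs reproduces byte-identical bundles.  Families lacking a
    reference tree (or alignment) are skipped with the reason recorded.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_family: dict[str, list[str]] = {}
    for pid, a in assignments.items():
        if a.assigned:
            by_family.setdefault(a.best_family_id, []).append(pid)
    result = BundleResult(bundles=[], skipped=[])
    for fam in sorted(by_family):
        pids = sorted(by_family[fam])
        missing = [p for p in pids if p not in sequences]
        if missing:
            raise PipelineError(f"bundle {fam}: sequences missing for {missing}")
        tree_src = Path(tree_dir) / f"{fam}.nwk" if tree_dir else None
        aln_src = Path(alignment_dir) / f"{fam}.aln.fasta" if alignment_dir else None
        if tree_src is not None and not tree_src.exists():
            result.skipped.append((fam, f"no reference tree {tree_src.name}"))
            continue
        if aln_src is not None and not aln_src.exists():
            result.skipped.append((fam, f"no reference alignment {aln_src.name}"))
            continue
        bdir = out / fam
        bdir.mkdir(exist_ok=True)
        with open(bdir / "new_seqs.fasta", "w", encoding="utf-8") as fh:
            for pid in pids:
                fh.write(f">{pid}\n{sequences[pid]}\n")
        if tree_src is not None:
            shutil.copyfile(tree_src, bdir / "reference.nwk")
        if aln_src is not None:
            shutil.copyfile(aln_src, bdir / "reference.aln.fasta")
        with open(bdir / "manifest.tsv", "w", encoding="utf-8") as fh:
            fh.write("family_id\tn_sequences\tprotein_ids\n")
            fh.write(f"{fam}\t{len(pids)}\t{','.join(pids)}\n")
        result.bundles.append(fam)
    return result
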