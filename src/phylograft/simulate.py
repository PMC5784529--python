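"""Duplication–loss gene-family simulator and toy-genome fixtures.

Gene families evolve along a fixed species tree as a birth–death process:
a lineage traversing a species-tree branch duplicates (splits, node
labelled *duplication*) at rate ``dup_rate`` and dies (loss) at rate
``loss_rate``, both per unit branch length; at every species-tree internal
node each surviving lineage splits into one copy per descendant species
branch (node labelled *speciation*); lineages reaching species-tree tips
become gene-tree leaves named ``g<k>_<SPECIES>``.  Extinct lineages are
pruned as they arise and unary nodes collapsed (their event labels drop out
of the ground truth, since no tree node remains to compare against).
Branch lengths are evolutionary time along the species tree — no rate
heterogeneity — so in the loss-free case on the (ultrametric) default
species tree, midpoint rooting recovers the true root.

The ground-truth event labels are the oracle for the species-overlap
classifier: with no losses the two must agree at every internal node, and
with losses every species-overlap duplication call is still a true
duplication (overlap cannot arise at a pure speciation node without
transfer events, which this model excludes).

:func:`make_toy_genome` writes a complete miniature input set (proteome
FASTA, GFF3, domtblout-style hit table, family trees, species map, ID map,
pipeline config) for end-to-end runs without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .species import DEFAULT_QUERY_SPECIES, DEFAULT_REFERENCE_SPECIES, SpeciesMap
from .tree import GeneTree, Node, parse_newick, write_newick

__all__ = [
    "SimConfig",
    "SimulatedFamily",
    "default_species_tree",
    "simulate_gene_trees",
    "make_toy_genome",
    "DEFAULT_SPECIES_TREE_NEWICK",
]

#: Ten-taxon ultrametric fixture mirroring the study design: four query
#: cichlids, Nile tilapia, zebrafish, human, mouse, fly, worm.  Depth 1.0.
DEFAULT_SPECIES_TREE_NEWICK = (
    "(((((((MZE:0.05,PNY:0.05):0.05,ABU:0.1):0.05,NBR:0.15):0.15,ONI:0.3):0.2,"
    "DRE:0.5):0.25,(HSA:0.35,MMU:0.35):0.4):0.25,(DME:0.6,CEL:0.6):0.4);"
)


def default_species_tree() -> GeneTree:
    return parse_newick(DEFAULT_SPECIES_TREE_NEWICK)


@dataclass
class SimConfig:
    """Simulation settings; identical config (incl. seed) ⇒ identical output."""

    species_tree: GeneTree = field(default_factory=default_species_tree)
    dup_rate: float = 0.3  # duplications per unit branch length
    loss_rate: float = 0.0
    seed: int = 0
    n_families: int = 100

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")


@dataclass
class SimulatedFamily:
    """One simulated gene family with ground truth.

    ``true_events`` maps ``id(node)`` of each surviving internal node of
    ``gene_tree`` to "speciation" or "duplication".  ``gene_tree`` is
    ``None`` when every lineage was lost.
    """

    index: int
    gene_tree: GeneTree | None
    true_events: dict[int, str]
    copy_number: dict[str, int]

    @property
    def is_empty(self) -> bool:
        return self.gene_tree is None


class _FamilySim:
    def __init__(self, species_root: Node, dup: float, loss: float, rng: np.random.Generator):
        self.dup = dup
        self.loss = loss
        self.rng = rng
        self.events: dict[int, str] = {}
        self.counter = 0
        self.species_root = species_root

    def _leaf(self, species: str, length: float) -> Node:
        self.counter += 1
        return Node(label=f"g{self.counter}_{species}", length=length)

    def _merge(self, children: list[Node], elapsed: float, event: str) -> Node | None:
        """Build an internal node, collapsing extinct/unary outcomes.

        ``elapsed`` is the time from the lineage segment's start to the
        event; surviving single children absorb it into their own length.
        """
        alive = [c for c in children if c is not None]
        if not alive:
            return None
        if len(alive) == 1:
            alive[0].length += elapsed
            return alive[0]
        node = Node(length=elapsed, children=alive)
        self.events[id(node)] = event
        return node

    def lineage(self, sp_node: Node, t_left: float) -> Node | None:
        """Evolve one lineage with ``t_left`` remaining on the branch into ``sp_node``."""
        total = self.dup + self.loss
        dt = self.rng.exponential(1.0 / total) if total > 0 else np.inf
        if dt < t_left:
            if self.rng.random() < self.loss / total:
                return None
            halves = [self.lineage(sp_node, t_left - dt) for _ in range(2)]
            return self._merge(halves, dt, "duplication")
        return self.at_node(sp_node, t_left)

    def at_node(self, sp_node: Node, elapsed: float) -> Node | None:
        if sp_node.is_leaf:
            return self._leaf(sp_node.label, elapsed)
        parts = [self.lineage(c, c.length) for c in sp_node.children]
        return self._merge(parts, elapsed, "speciation")

    def run(self) -> tuple[GeneTree | None, dict[int, str]]:
        root = self.at_node(self.species_root, 0.0)
        if root is None:
            return None, {}
        tree = GeneTree(root)  # resets the (meaningless) root stem length
        return tree, {k: v for k, v in self.events.items() if k in set(map(id, tree.nodes()))}


def simulate_gene_trees(config: SimConfig) -> list[SimulatedFamily]:
    """Simulate ``config.n_families`` gene families along the species tree.

    Families that lose every lineage are returned as empty records, not
    errors.  Output is a pure function of the config.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for k in range(config.n_families):
        sim = _FamilySim(config.species_tree.root, config.dup_rate, config.loss_rate, rng)
        tree, events = sim.run()
        copies: dict[str, int] = {}
        if tree is not None:
            for lf in tree.leaves():
                sp = lf.label.rsplit("_", 1)[1]
                copies[sp] = copies.get(sp, 0) + 1
        out.append(SimulatedFamily(index=k, gene_tree=tree, true_events=events, copy_number=copies))
    return out


# ---------------------------------------------------------------------------
# toy genome fixture


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _domtbl_row(family: str, protein: str, qlen: int, score: float, i_eval: float,
                ali_from: int, ali_to: int) -> str:
    cols = [
        family, "-", "200", protein, "-", str(qlen),
        f"{i_eval:.1e}", f"{score:.1f}", "0.1",
        "1", "1", f"{i_eval:.1e}", f"{i_eval:.1e}", f"{score:.1f}", "0.1",
        "1", "180", str(ali_from), str(ali_to), str(ali_from), str(ali_to),
        "0.95", "toy fixture",
    ]
    return " ".join(cols)


def make_toy_genome(out_dir, seed: int = 0) -> Path:
    """Write a ~20-gene toy genome with every input the pipeline consumes.

    The fixture contains multi-isoform genes (one gene with three isoforms
    of distinct lengths), one engineered chimeric protein hitting two
    families in disjoint regions, two genes with no family hit at all, and
    per-family trees in which the chosen proteins already sit next to
    reference-species leaves (as if grafting had been run).  Purely
    synthetic; deterministic for a given seed.
    """
    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_genes = 20
    genes = [f"mzg{i:02d}" for i in range(1, n_genes + 1)]
    # isoform counts: gene 1 has three isoforms, genes 2-4 have two, rest one
    isoforms: dict[str, list[tuple[str, int]]] = {}
    fasta_lines = []
    gff_lines = ["##gff-version 3"]
    chosen: dict[str, tuple[str, int]] = {}
    pos = 1
    for gi, gene in enumerate(genes):
        n_iso = 3 if gi == 0 else (2 if gi < 4 else 1)
        lengths = [100 + 7 * gi, 180 + 7 * gi, 320 + 7 * gi][:n_iso]
        recs = []
        gff_lines.append(
            f"chr1\ttoy\tgene\t{pos}\t{pos + 5000}\t.\t+\t.\tID={gene}"
        )
        for j, ln in enumerate(lengths, 1):
            pid = f"{gene}.p{j}"
            recs.append((pid, ln))
            seq = _random_protein(rng, ln)
            fasta_lines.append(f">{pid} gene={gene}")
            fasta_lines.append(seq)
            gff_lines.append(
                f"chr1\ttoy\tmRNA\t{pos}\t{pos + 5000}\t.\t+\t.\t"
                f"ID={pid};Parent={gene}"
            )
        pos += 6000
        isoforms[gene] = recs
        chosen[gene] = max(recs, key=lambda r: r[1])  # isoform lengths are distinct here
    # families: 6 families of uneven size over genes 1-18 (so the report shows
    # one-to-one, one-to-two and one-to-X categories); genes 19-20 have no hits
    families = [f"TF{100 + i}" for i in range(6)]
    fam_sizes = [1, 2, 3, 4, 4, 4]
    fam_sequence = [f for f, k in zip(families, fam_sizes) for _ in range(k)]
    fam_of: dict[str, str] = {}
    hit_lines = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for gi, gene in enumerate(genes[:18]):
        fam = fam_sequence[gi]
        fam_of[gene] = fam
        pid, ln = chosen[gene]
        score = float(rng.integers(120, 400))
        hit_lines.append(_domtbl_row(fam, pid, ln, score, 1e-40, 5, max(40, ln - 10)))
        # a weaker decoy hit to a different family, fully overlapping
        decoy = families[(gi + 1) % len(families)]
        hit_lines.append(_domtbl_row(decoy, pid, ln, score / 3, 1e-8, 5, max(40, ln - 10)))
    # engineered chimera: gene mzg18's protein also hits a second family in a
    # disjoint C-terminal region, like a fused two-gene annotation
    chim_gene = genes[17]
    chim_pid, chim_len = chosen[chim_gene]
    other_fam = families[(17 + 3) % len(families)]
    half = max(60, chim_len // 2)
    hit_lines = [
        ln for ln in hit_lines if not (chim_pid in ln)
    ]
    hit_lines.append(_domtbl_row(fam_of[chim_gene], chim_pid, chim_len, 300.0, 1e-60, 1, half - 10))
    hit_lines.append(_domtbl_row(other_fam, chim_pid, chim_len, 200.0, 1e-45, half + 10, chim_len))

    (out / "proteome.fasta").write_text("\n".join(fasta_lines) + "\n")
    (out / "annotation.gff3").write_text("\n".join(gff_lines) + "\n")
    (out / "hits.domtbl").write_text("\n".join(hit_lines) + "\n")

    # family trees: each family gets its member query proteins plus HSA/DRE
    # reference leaves and sister-cichlid leaves for median copy counts
    members: dict[str, list[str]] = {f: [] for f in families}
    for gene, fam in fam_of.items():
        members[fam].append(chosen[gene][0])
    species_rows = []
    id_rows = ["#source_id\tsymbol"]
    symbols = ["BMP4", "BMP2", "AVPR1A", "FERMT1", "PTGFR", "ZFYVE9"]
    for fi, fam in enumerate(families):
        hsa = f"ENSP{7000 + fi}_HSA"
        dre = f"ENSDARP{8000 + fi}_DRE"
        clade_parts = []
        for k, pid in enumerate(sorted(members[fam])):
            pny = f"pny{fi}{k}_PNY"
            species_rows.append(f"{pid}\tMZE")
            clade_parts.append(f"({pid}:0.05,{pny}:0.05)")
        if len(clade_parts) == 1:
            cichlids = clade_parts[0] + ":0.95"
        else:
            cichlids = "(" + ",".join(p + ":0.45" for p in clade_parts) + "):0.5"
        if fam == families[-1]:
            # the last family's tree has no human leaf: a NoHomolog exemplar
            nwk = f"(({cichlids},{dre}:1.0):0.5,mmu{fi}_MMU:1.5)"
        else:
            id_rows.append(f"{hsa}\t{symbols[fi % len(symbols)]}")
            nwk = f"(({cichlids},{dre}:1.0):0.5,{hsa}:1.5)"
        (out / "trees" / f"{fam}.nwk").write_text(f"{nwk};\n")
    (out / "species_map.tsv").write_text(
        "# leaf label\tspecies code\n" + "\n".join(sorted(species_rows)) + "\n"
    )
    (out / "id_map.tsv").write_text("\n".join(id_rows) + "\n")

    config = f"""# toy genome pipeline configuration
proteins: {out / 'proteome.fasta'}
annotation: {out / 'annotation.gff3'}
hits: {out / 'hits.domtbl'}
trees_dir: {out / 'trees'}
id_map: {out / 'id_map.tsv'}
species_map: {out / 'species_map.tsv'}
focal_species: MZE
query_species: [MZE, PNY, ABU, NBR]
reference_species: [HSA, DRE]
delimiter: "_"
"""
    (out / "config.yaml").write_text(config)
    return out
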