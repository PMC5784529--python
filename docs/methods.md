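# Methods

## The classification model

`phylograft` infers gene-level homology from per-family phylogenies rather
than from pairwise sequence similarity. The underlying assumptions are the
standard ones of gene-tree/species-tree reasoning:

- Each family tree is a (possibly unrooted, possibly multifurcating) gene
  tree whose leaves are proteins from known species, with branch lengths in
  substitutions per site.
- Internal nodes represent either speciation or duplication events. Under
  a duplication–loss model without horizontal transfer, the child subtrees
  of a speciation node descend into disjoint species sets, so any species
  shared between two child subtrees is evidence of duplication. This is
  the **species-overlap rule**: label a node *duplication* iff ≥ 2 of its
  child subtrees have intersecting species sets (any pairwise intersection,
  so multifurcations need no resolution), else *speciation*. Overlap can
  only be destroyed, never created, by gene loss — hence the rule's
  characteristic asymmetry: duplication calls are always safe (precision
  1.0 on simulated data), but a duplication followed by complementary
  losses can masquerade as a speciation (recall < 1). The package asserts
  the former and only reports the latter.
- Orthology of a leaf pair is decided by the event at their MRCA.

The per-gene cascade (midpoint rooting → event labels → smallest subtree
containing a reference-species leaf → closest reference leaf → relationship
→ multiplicity) is described in the README; this note records the decisions
that were genuinely open.

### Interpretation and tie-break decisions

- **"Closest" means minimal patristic distance** (path-length sum between
  the two leaves), not shortest terminal branch. A terminal-branch reading
  ignores the query's own position in the tree; the path sum is the
  standard proximity measure on phylogenies and the only one involving both
  leaves.
- **The closest-homolog search is confined to the smallest containing
  subtree**, not the whole tree: the containing clade defines the homology
  context first, and only then is the nearest reference protein chosen
  within it.
- **Rooting precedes event labelling, always.** `call_gene` midpoint-roots
  even pre-rooted input unless `reroot=False` is passed, because event
  labels are root-dependent and the pipeline's contract is that every tree
  goes through the same rooting.
- **Midpoint tie-breaks.** When several leaf pairs attain the tree
  diameter, the pair that is lexicographically smallest (as a sorted label
  pair) defines the midpoint path; a midpoint falling exactly on an
  existing node (tolerance 1e-12 · max(1, diameter)) makes that node the
  root instead of inserting a zero-length edge. Both choices are purely
  for determinism across platforms.
- **All remaining ties are lexicographic on leaf label** (closest-homolog
  ties in particular), making every call byte-reproducible.
- **Zero-length branches are legal; negative lengths are rejected** at
  parse time with the offending position.
- **Multiplicity vocabulary.** "one-to-X" requires exactly one
  reference-species leaf in the containing clade, X ≥ 1 being the
  query-species copy count. Clades with ≥ 2 reference leaves get the
  extension labels "many-to-many" (X ≥ 2) or "many-to-one" (X = 1); these
  go beyond the classic one-to-X vocabulary and are kept distinct in
  summaries so users can treat them separately.
- **Median copy number counts zeros** for configured query genomes with no
  leaf in the clade (default), reading "median over all query genomes" as
  all genomes in the study design and letting losses pull the median down;
  `count_absent_species=False` restricts the median to genomes present.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `SpeciesMap.query_species` | MZE, PNY, ABU, NBR | species codes | genomes being classified; the median is taken over these |
| `SpeciesMap.reference_species` | HSA, DRE | species codes | classification targets, in report order |
| `SpeciesMap.delimiter` | `_` | — | pattern rule: species code = token after the last delimiter; an explicit table overrides it |
| `assign_families(mode=)` | `"sum"` | — | family score = summed domain bits; `"max"` uses the best single domain |
| `flag_chimeric(max_overlap_frac=)` | 0.1 | fraction | two top families may overlap by ≤ 10% of the shorter hit region |
| `flag_chimeric(min_region_len=)` | 50 | aa | both regions must be at least a domain-sized stretch |
| `SimConfig.dup_rate` | 0.3 | events per unit branch length | keeps simulated families in the ≤ 40-leaf regime on the depth-1.0 species tree (expected ≈ e^0.3 ≈ 1.35 copies per species) |
| `SimConfig.loss_rate` | 0.0 | events per unit branch length | 0 for the exact-recovery oracle; 0.2 in the precision/recall regime |

The chimera defaults are deliberately permissive: real gene-model fusions
join two long, well-separated domains, and 10%/50 aa catches such cases
while full-overlap competing homology is never flagged. The flag is
monotone in `max_overlap_frac` (shrinking it can only remove flags) and
never fires on single-family proteins.

## The simulator: what it emulates and what it does not

`simulate_gene_trees` runs a birth–death process along a fixed species
tree: duplications split a lineage (rate `dup_rate`), losses terminate it
(rate `loss_rate`), both as Poisson processes per unit branch length;
species-tree nodes force speciation of every surviving lineage; extinct
lineages are pruned as they arise and unary nodes collapsed with their
event labels dropped from the ground truth (no tree node remains to
compare against). An all-lineages-lost family is recorded as empty, not an
error.

The default 10-taxon species tree mirrors the study design (four query
cichlids, Nile tilapia, zebrafish, human, mouse, fly, worm) and is
**ultrametric with depth 1.0**. Gene-tree branch lengths are evolutionary
time — no rate heterogeneity — so loss-free gene trees are ultrametric and
midpoint rooting provably recovers the true root. That is a test aid, not
a biological claim: it makes "species-overlap equals simulator truth at
100% of nodes" a meaningful oracle by removing rooting error as a
confounder.

Consequences for interpreting green tests: the simulator exercises
topology, rooting, event logic, multiplicity and copy-number accounting,
but real trees add what it omits — rate heterogeneity across lineages
(midpoint rooting can then misroot), estimation error in branch lengths
and topology, incomplete lineage sorting, and database artifacts such as
missing genes (the simulator's losses model the genuine-absence case but
not systematic annotation gaps). Passing the simulated oracles therefore
validates the algorithmic chain, not the accuracy of any particular ML
tree.

The toy genome (`make_toy_genome`) is a fully synthetic ~20-gene fixture:
multi-isoform genes, six families of uneven size (so reports show
one-to-one through one-to-four), one family tree without a human leaf (a
NoHomolog exemplar), two genes with no family hit, and one engineered
chimeric protein whose two family hits occupy disjoint halves. Its family
trees already contain the query leaves, standing in for the external
grafting step.

## The grafting contract

Re-aligning new proteins into a family alignment and re-estimating the
tree are jobs for dedicated external tools; re-implementing them here
would be both redundant and worse. `prepare_graft_bundle` writes one
directory per family — `new_seqs.fasta`, the reference alignment and
Newick, a `manifest.tsv` — for the user to run e.g. `mafft --add` and an
ML placement; the pipeline then consumes the updated Newick from
`trees_dir`. Bundles are deterministic and idempotent; a family lacking
its reference tree or alignment is skipped with the reason recorded.
Genes whose assigned family has no usable tree at classification time
(file missing, or the query leaf absent because grafting was not run)
appear in reports with relationship `no_tree` rather than being conflated
with `no_homolog`.

## Numerical and degenerate-input choices

- Branch lengths serialise with 10 significant digits; round-trip
  structural equality is checked to 1e-9.
- Patristic distance sums edges in a canonical (label-sorted) order so
  d(a, b) and d(b, a) are bit-identical.
- A missing branch length on a required path raises an error — never a
  silent zero.
- Duplicate leaf labels, unbalanced parentheses and negative lengths are
  parse errors carrying the character position.
- Pruning collapses unary nodes by summing lengths, preserving pairwise
  distances among retained leaves exactly; pruning away every leaf is an
  error.
- Midpoint rooting on < 2 leaves or without lengths is an error.
- Hit-table rows that fail to parse are skipped with their line numbers
  logged (`strict=True` raises); a table with zero parseable rows is
  always an error.
- Isoform-length ties break to the lexicographically smallest protein ID;
  a trailing `*` stop symbol is excluded from the length.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use 200 simulated families per
regime (≈ 13 leaves each at the default rates), 100 random trees of 5–50
leaves for the rooting and closest-homolog oracles, 500 families on a
5-species tree for the duplication-count expectation check, and the
20-gene toy genome for end-to-end runs — sizes at which the brute-force
oracles (all-pairs distance matrices, full edge scans, exhaustive ancestor
scans) are exact and fast.

## Known limitations

- No reconciliation against a dated species tree: duplication timing is
  never inferred; "one-to-two" is reported as a label only.
- Species-overlap recall under heavy loss is inherently limited (see
  above); no attempt is made to rescue hidden duplications.
- Midpoint rooting assumes roughly clock-like trees; strong rate
  heterogeneity shifts the root and thus event labels.
- The GFF3 linker follows `Parent`/`ID` chains (attribute keys
  configurable) and does not attempt CDS translation or genome-sequence
  handling.
- `run_pipeline` classifies one focal proteome per invocation, as the
  per-species report tables suggest; multi-species batch runs are a loop
  over configs.
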