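# phylograft

Genome-wide homology classification by grafting query proteomes into
reference gene-family trees.

When a newly sequenced genome (the motivating case: East African cichlid
fishes) needs functional annotation, almost everything known about its genes
comes from homology to well-studied species. `phylograft` implements the
tree-based half of that workflow: given per-family phylogenies that contain
both the query species' proteins and reference-species proteins, it
classifies every query gene's evolutionary relationship to its nearest
human and zebrafish genes — ortholog, paralog or no-homolog — together with
the one-to-X co-ortholog multiplicity (teleost and lineage-specific
duplications make one-to-two common in fish) and the median copy number
across the query genomes.

## What it computes

For each query protein *q* in a family tree *T*:

1. **Midpoint rooting.** *T* is rooted at the midpoint of its longest
   leaf-to-leaf path, the position minimising the maximum root-to-leaf
   patristic distance.
2. **Species-overlap event labelling.** Each internal node *v* is labelled
   *duplication* iff at least two of its child subtrees share a species
   (Huerta-Cepas-style species overlap); otherwise *speciation*. No binary
   assumption — any pairwise overlap among a multifurcation's children
   counts.
3. **Smallest containing subtree.** Walk from *q* toward the root to the
   first ancestor whose subtree holds ≥ 1 leaf of the reference species; if
   none exists the call is **NoHomolog**.
4. **Closest homolog.** Within that subtree, the reference leaf *r*
   minimising the patristic distance d(q, r) = Σ branch lengths on the q–r
   path (ties broken lexicographically).
5. **Ortholog/paralog.** *q* and *r* are orthologs iff their MRCA is a
   speciation node.
6. **Multiplicity.** For orthologs, X = number of query-species leaves in
   the containing subtree (→ "one-to-one", "one-to-two", …), plus the
   median copy count over all configured query genomes, counting zero for
   genomes absent from the clade.

Upstream of the tree work, the package selects the longest protein isoform
per gene from GFF3 + FASTA, picks each protein's best family from
profile-HMM per-domain hit tables (summed domain bit score; ties by
E-value, then family ID), flags chimeric gene models (two top families
hitting disjoint regions — the signature of an annotation fusing adjacent
genes), and prepares per-family bundles for external alignment/placement
tools (`mafft --add` + RAxML or similar). A duplication–loss simulator
generates gene trees with known event labels, which is how the classifier
is validated end to end.

## Worked example

Two *M. zebra* copies sit in a clade with one zebrafish and one human
protein:

```python
from phylograft import call_gene, parse_newick, SpeciesMap

smap = SpeciesMap(query_species=("MZE", "PNY", "ABU", "NBR"),
                  reference_species=("HSA", "DRE"))
tree = parse_newick("(((q1_MZE:0.1,q2_MZE:0.1):0.6,d1_DRE:0.7):0.8,h1_HSA:1.5);")
for call in call_gene(tree, "q1_MZE", smap):
    print(f"{call.reference_species}: {call.relationship}"
          f" closest={call.closest_reference_protein}"
          f" distance={call.distance}"
          f" multiplicity={call.multiplicity}"
          f" median_copies={call.median_query_copies}")
```

prints

```
HSA: ortholog closest=h1_HSA distance=3.0 multiplicity=one-to-two median_copies=0.0
DRE: ortholog closest=d1_DRE distance=1.4 multiplicity=one-to-two median_copies=0.0
```

The MRCA of `q1_MZE` with either reference leaf is a speciation node (its
child subtrees share no species), so both calls are orthologs; the
containing clade holds two MZE copies, hence *one-to-two* — the pattern a
gene duplicated in the teleost ancestor leaves behind. The median copy
count over the four configured query genomes is the median of {MZE: 2,
PNY: 0, ABU: 0, NBR: 0} = 0, flagging that only one genome is represented
in this (deliberately tiny) tree.

The same cascade runs genome-wide from the command line. On the bundled toy
genome fixture (20 genes, 6 families, one engineered chimera, two no-hit
genes):

```sh
python -c "from phylograft.simulate import make_toy_genome; make_toy_genome('toy')"
phylograft run --config toy/config.yaml --out toy_out
```

```
20 genes; fraction with family hit 0.900
  one-to-one ortholog: 1
  one-to-two ortholog: 2
  one-to-X (X>2) ortholog: 11
  no_homolog: 4
  no_family_hit: 2
```

`toy_out/report_MZE.tsv` holds the per-gene table (closest human and
zebrafish proteins, symbols, distances, multiplicities, chimera flags);
`toy_out/summary.txt` the category counts above. Other subcommands:
`select-isoforms`, `assign-families`, `bundle`, `classify`, `simulate`,
`prune`, `report`.

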