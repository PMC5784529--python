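"""Classify each query gene's evolutionary relationship to reference-species genes.

Given a gene-family tree containing both query-species proteins and
reference-species proteins, the engine:

1. midpoint-roots the tree (unless asked to keep an existing root);
2. labels every internal node *speciation* or *duplication* with the
   species-overlap rule — a node is a duplication iff at least two of its
   child subtrees share a species (any pairwise overlap, so multifurcations
   need no binary assumption);
3. walks from the query leaf toward the root to the smallest subtree that
   contains at least one reference-species leaf (no such subtree ⇒
   *NoHomolog*);
4. picks the closest reference protein inside that subtree by patristic
   distance (ties broken lexicographically by leaf label);
5. calls *ortholog* or *paralog* from the event at the MRCA of the query
   and that closest reference leaf;
6. for orthologs, reports the one-to-X multiplicity (X = query-species
   copies in the subtree) and the median copy number over all configured
   query genomes, counting zero for genomes absent from the subtree.

"Closest" is minimal patristic (path-sum) distance: the standard measure of
proximity on a tree and the only reading that involves both leaves.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable

from .errors import ContractError, TreeError
from .species import SpeciesMap
from .tree import GeneTree, Node

__all__ = [
    "EventLabel",
    "HomologyCall",
    "SPECIATION",
    "DUPLICATION",
    "label_events",
    "smallest_containing_subtree",
    "closest_homolog",
    "classify_relationship",
    "ortho_multiplicity",
    "call_gene",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"

_NUMBER_WORDS = {
    1: "one", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six",
    7: "seven", 8: "eight", 9: "nine", 10: "ten", 11: "eleven", 12: "twelve",
}


def _number_word(x: int) -> str:
    return _NUMBER_WORDS.get(x, str(x))


@dataclass(frozen=True)
class EventLabel:
    """Species-overlap verdict for one internal node."""

    event: str  # SPECIATION or DUPLICATION
    overlap_size: int  # number of species shared between child subtrees

    def __post_init__(self):
        if (self.event == DUPLICATION) != (self.overlap_size >= 1):
            raise ContractError("duplication label requires overlap_size >= 1 and vice versa")


@dataclass(frozen=True)
class HomologyCall:
    """One query gene's classification against one reference species.

    Reference fields are ``None`` exactly when ``relationship`` is
    ``"no_homolog"``; multiplicity fields are present exactly when the
    relationship is ``"ortholog"``.
    """

    query_gene: str
    family: str | None
    reference_species: str
    relationship: str  # "ortholog" | "paralog" | "no_homolog"
    closest_reference_protein: str | None = None
    closest_reference_symbol: str | None = None
    distance: float | None = None
    multiplicity: str | None = None
    x_value: int | None = None
    median_query_copies: float | None = None

    def __post_init__(self):
        ref_fields = (self.closest_reference_protein, self.distance)
        if self.relationship == "no_homolog":
            if any(f is not None for f in ref_fields):
                raise ContractError("no_homolog calls must carry no reference fields")
        elif any(f is None for f in ref_fields):
            raise ContractError(f"{self.relationship} call missing reference protein/distance")
        ortho_fields = (self.multiplicity, self.x_value, self.median_query_copies)
        if self.relationship == "ortholog":
            if any(f is None for f in ortho_fields):
                raise ContractError("ortholog calls must carry multiplicity fields")
        elif any(f is not None for f in ortho_fields):
            raise ContractError("multiplicity fields are ortholog-only")


def _species_sets(tree: GeneTree, smap: SpeciesMap) -> dict[int, frozenset[str]]:
    """Species set of the subtree under every node, keyed by id(node)."""
    sets: dict[int, frozenset[str]] = {}
    for n in tree.root.postorder():
        if n.is_leaf:
            sets[id(n)] = frozenset((smap.resolve(n.label),))
        else:
            acc: set[str] = set()
            for c in n.children:
                acc |= sets[id(c)]
            sets[id(n)] = frozenset(acc)
    return sets


def label_events(tree: GeneTree, smap: SpeciesMap) -> dict[int, EventLabel]:
    """Species-overlap event labels for every internal node, keyed by id(node).

    Duplication iff at least two child subtrees have intersecting species
    sets; ``overlap_size`` counts the species seen in more than one child
    subtree.
    """
    sets = _species_sets(tree, smap)
    labels: dict[int, EventLabel] = {}
    for n in tree.internal_nodes():
        seen: set[str] = set()
        shared: set[str] = set()
        for c in n.children:
            cs = sets[id(c)]
            shared |= seen & cs
            seen |= cs
        event = DUPLICATION if shared else SPECIATION
        labels[id(n)] = EventLabel(event=event, overlap_size=len(shared))
    return labels


def smallest_containing_subtree(
    tree: GeneTree, query_leaf: str, reference: str, smap: SpeciesMap
) -> Node | None:
    """First ancestor of the query leaf whose subtree holds a reference-species leaf.

    Returns ``None`` (the NoHomolog sentinel) when even the root contains no
    reference leaf.
    """
    node = tree.find_leaf(query_leaf)
    anc = node.parent
    while anc is not None:
        if any(smap.resolve(lf.label) == reference for lf in anc.leaves()):
            return anc
        anc = anc.parent
    return None


def closest_homolog(
    tree: GeneTree, query_leaf: str, reference: str, smap: SpeciesMap
) -> tuple[str, float] | None:
    """Closest reference-species leaf (by patristic distance) in the smallest
    containing subtree, or ``None`` when there is no such subtree."""
    sub = smallest_containing_subtree(tree, query_leaf, reference, smap)
    if sub is None:
        return None
    candidates = sorted(
        lf.label for lf in sub.leaves() if smap.resolve(lf.label) == reference
    )
    best_label, best_dist = None, None
    for label in candidates:  # lexicographic order makes ties deterministic
        d = tree.distance(query_leaf, label)
        if best_dist is None or d < best_dist:
            best_label, best_dist = label, d
    return best_label, best_dist


def classify_relationship(
    tree: GeneTree,
    query_leaf: str,
    reference_leaf: str,
    events: dict[int, EventLabel],
    smap: SpeciesMap,
) -> str:
    """"ortholog" iff the two leaves' MRCA is a speciation node, else "paralog"."""
    anc = tree.mrca([query_leaf, reference_leaf])
    if id(anc) not in events:
        raise TreeError("event labels do not cover the MRCA; were they computed on this tree?")
    return "ortholog" if events[id(anc)].event == SPECIATION else "paralog"


def ortho_multiplicity(
    tree: GeneTree,
    query_leaf: str,
    reference_leaf: str,
    events: dict[int, EventLabel],
    smap: SpeciesMap,
    count_absent_species: bool = True,
) -> tuple[str, int, float]:
    """One-to-X multiplicity and median query-genome copy number for an ortholog pair.

    The ortholog clade is the smallest subtree containing the query leaf and
    a leaf of the reference species.  X counts the query gene's own species'
    leaves in that clade.  With exactly one reference leaf the relationship
    is "one-to-X"; with several reference leaves it is "many-to-many"
    (X ≥ 2) or "many-to-one" (X = 1) — the many-to-* labels are an
    extension beyond the classic one-to-X vocabulary and are flagged as such
    in reports.  The median is taken over all configured query genomes'
    copy counts in the clade, counting zero for a configured genome with no
    leaf there (set ``count_absent_species=False`` to ignore absentees).
    """
    if classify_relationship(tree, query_leaf, reference_leaf, events, smap) != "ortholog":
        raise ContractError(
            f"ortho_multiplicity called on a non-ortholog pair ({query_leaf}, {reference_leaf})"
        )
    reference = smap.resolve(reference_leaf)
    clade = smallest_containing_subtree(tree, query_leaf, reference, smap)
    own_species = smap.resolve(query_leaf)
    counts: dict[str, int] = {}
    n_reference = 0
    for lf in clade.leaves():
        sp = smap.resolve(lf.label)
        counts[sp] = counts.get(sp, 0) + 1
        if sp == reference:
            n_reference += 1
    x = counts.get(own_species, 0)
    if n_reference == 1:
        multiplicity = f"one-to-{_number_word(x)}"
    elif x >= 2:
        multiplicity = "many-to-many"
    else:
        multiplicity = "many-to-one"
    if count_absent_species:
        copies = [counts.get(sp, 0) for sp in smap.query_species]
    else:
        copies = [counts[sp] for sp in smap.query_species if sp in counts]
    median = float(statistics.median(copies)) if copies else 0.0
    return multiplicity, x, median


def call_gene(
    tree: GeneTree,
    query_leaf: str,
    smap: SpeciesMap,
    family: str | None = None,
    gene_id: str | None = None,
    reroot: bool = True,
    count_absent_species: bool = True,
) -> list[HomologyCall]:
    """Full classification of one query protein: one call per reference species.

    The tree is midpoint-rooted first (pass ``reroot=False`` to trust an
    existing root), events are labelled once, and each reference species
    gets the subtree search → closest homolog → ortholog/paralog →
    multiplicity cascade.  Deterministic: identical inputs give identical
    records.
    """
    try:
        rooted = tree.midpoint_root() if reroot else tree
        events = label_events(rooted, smap)
        gene = gene_id if gene_id is not None else query_leaf
        calls = []
        for reference in smap.reference_species:
            hit = closest_homolog(rooted, query_leaf, reference, smap)
            if hit is None:
                calls.append(
                    HomologyCall(
                        query_gene=gene, family=family,
                        reference_species=reference, relationship="no_homolog",
                    )
                )
                continue
            ref_leaf, dist = hit
            rel = classify_relationship(rooted, query_leaf, ref_leaf, events, smap)
            if rel == "ortholog":
                mult, x, median = ortho_multiplicity(
                    rooted, query_leaf, ref_leaf, events, smap,
                    count_absent_species=count_absent_species,
                )
            else:
                mult = x = median = None
            calls.append(
                HomologyCall(
                    query_gene=gene, family=family, reference_species=reference,
                    relationship=rel, closest_reference_protein=ref_leaf,
                    distance=dist, multiplicity=mult, x_value=x,
                    median_query_copies=median,
                )
            )
        return calls
    except Exception as exc:
        exc.add_note(f"while classifying gene {gene_id or query_leaf!r} (family {family!r})")
        raise


def batch_call_genes(
    tree: GeneTree,
    query_leaves: Iterable[str],
    smap: SpeciesMap,
    family: str | None = None,
    reroot: bool = True,
    count_absent_species: bool = True,
) -> dict[str, list[HomologyCall]]:
    """Classify several query leaves of one family tree, rooting and labelling once."""
    rooted = tree.midpoint_root() if reroot else tree
    out: dict[str, list[HomologyCall]] = {}
    for leaf in query_leaves:
        out[leaf] = call_gene(
            rooted, leaf, smap, family=family, reroot=False,
            count_absent_species=count_absent_species,
        )
    return out
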