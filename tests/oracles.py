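"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here recomputes quantities by exhaustive enumeration (all nodes,
all edges, all pairs) or from simulator ground truth, never by calling the
code path under test.
"""

from __future__ import annotations

import numpy as np

from phylograft.tree import GeneTree, Node


def make_random_tree(rng: np.random.Generator, n_leaves: int, labels=None) -> GeneTree:
    """Random binary topology with uniform branch lengths in [0.05, 1.0]."""
    if labels is None:
        labels = [f"L{i:03d}" for i in range(n_leaves)]
    nodes = [Node(label=lb, length=float(rng.uniform(0.05, 1.0))) for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(length=float(rng.uniform(0.05, 1.0)), children=[a, b]))
    root = nodes[0]
    return GeneTree(root)


def make_random_species_tree(rng: np.random.Generator, n_leaves: int, species_pool) -> GeneTree:
    """Random tree whose leaves are labelled g<i>_<SPECIES> from the pool."""
    labels = [f"g{i:03d}_{rng.choice(species_pool)}" for i in range(n_leaves)]
    return make_random_tree(rng, n_leaves, labels)


def brute_mrca(tree: GeneTree, labels: set[str]) -> Node:
    """Among nodes whose leaf set contains the query set, the one with fewest leaves."""
    best = None
    for n in tree.nodes():
        leafset = {lf.label for lf in ([n] if n.is_leaf else n.leaves())}
        if labels <= leafset and (best is None or len(leafset) < best[0]):
            best = (len(leafset), n)
    return best[1]


def brute_distances(tree: GeneTree) -> dict[tuple[str, str], float]:
    """All-pairs patristic distances from root-to-leaf path enumeration."""
    paths: dict[str, list[Node]] = {}
    for lf in tree.leaves():
        path = [lf]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        paths[lf.label] = path[::-1]  # root .. leaf
    out: dict[tuple[str, str], float] = {}
    labels = sorted(paths)
    for i, a in enumerate(labels):
        out[(a, a)] = 0.0
        for b in labels[i + 1 :]:
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            d = sum(n.length for n in pa[k:]) + sum(n.length for n in pb[k:])
            out[(a, b)] = out[(b, a)] = d
    return out


def brute_minimax_root_distance(tree: GeneTree) -> float:
    """Minimum over all edge positions of the maximum point-to-leaf distance.

    For a candidate root on the edge (parent u, child v) of length L at
    distance t from v, leaves below v are at t + d(v, leaf) and all others
    at (L - t) + d(u, leaf); the per-edge optimum has the closed form
    t* = clamp((L + B - A) / 2, 0, L) with A, B the two side maxima.
    """
    # distances from every node to every leaf, via each leaf's root path
    node_leaf_dist: dict[int, dict[str, float]] = {id(n): {} for n in tree.nodes()}
    for lf in tree.leaves():
        d = 0.0
        node_leaf_dist[id(lf)][lf.label] = 0.0
        n = lf
        while n.parent is not None:
            d += n.length
            n = n.parent
            node_leaf_dist[id(n)][lf.label] = d
    # unrooted node-to-leaf distances: propagate down from root
    all_leaves = {lf.label for lf in tree.leaves()}

    def unrooted_dist(node: Node, leaf: str) -> float:
        below = node_leaf_dist[id(node)]
        if leaf in below:
            return below[leaf]
        # go up until the leaf is below
        d = 0.0
        n = node
        while leaf not in node_leaf_dist[id(n)]:
            d += n.length
            n = n.parent
        return d + node_leaf_dist[id(n)][leaf]

    best = float("inf")
    for v in tree.nodes():
        if v.parent is None:
            continue
        u, length = v.parent, v.length
        below_v = set(node_leaf_dist[id(v)])
        above = all_leaves - below_v
        a_max = max(node_leaf_dist[id(v)].values())
        b_max = max(unrooted_dist(u, lf) for lf in above) if above else 0.0
        t = min(max((length + b_max - a_max) / 2.0, 0.0), length)
        best = min(best, max(t + a_max, (length - t) + b_max))
    return best


def brute_smallest_containing(tree: GeneTree, query: str, reference: str, resolve) -> Node | None:
    """Among ancestors of the query leaf containing a reference leaf, the
    one with fewest leaves (the walk result, recomputed by full scan)."""
    q = tree.find_leaf(query)
    candidates = []
    n = q.parent
    while n is not None:
        leaves = n.leaves()
        if any(resolve(lf.label) == reference for lf in leaves):
            candidates.append((len(leaves), n))
        n = n.parent
    return min(candidates)[1] if candidates else None


def brute_closest_reference(tree, query, reference, resolve):
    """Argmin over the brute-force all-pairs matrix, restricted to the
    smallest containing subtree; lexicographic tie-break."""
    sub = brute_smallest_containing(tree, query, reference, resolve)
    if sub is None:
        return None
    dists = brute_distances(tree)
    refs = sorted(lf.label for lf in sub.leaves() if resolve(lf.label) == reference)
    best = min(refs, key=lambda r: (dists[(query, r)], r))
    return best, dists[(query, best)]


def truth_relationship_category(fam, smap, reference: str = "HSA") -> dict[str, str]:
    """Per query-gene relationship categories derived from simulator ground
    truth: the tree as simulated (true root) and the true event labels,
    never the species-overlap classifier."""
    tree = fam.gene_tree
    dists = brute_distances(tree)
    out: dict[str, str] = {}
    for lf in tree.leaves():
        if smap.resolve(lf.label) not in smap.query_species:
            continue
        sub = brute_smallest_containing(tree, lf.label, reference, smap.resolve)
        if sub is None:
            out[lf.label] = "no_homolog"
            continue
        refs = sorted(
            x.label for x in sub.leaves() if smap.resolve(x.label) == reference
        )
        closest = min(refs, key=lambda r: (dists[(lf.label, r)], r))
        anc = brute_mrca(tree, {lf.label, closest})
        if fam.true_events[id(anc)] == "duplication":
            out[lf.label] = "paralog"
            continue
        own = smap.resolve(lf.label)
        x = sum(1 for y in sub.leaves() if smap.resolve(y.label) == own)
        if len(refs) > 1:
            out[lf.label] = "many-to-many" if x >= 2 else "many-to-one"
        elif x == 1:
            out[lf.label] = "one-to-one"
        elif x == 2:
            out[lf.label] = "one-to-two"
        else:
            out[lf.label] = "one-to-X"
    return out


def category_of_call(call) -> str:
    """Collapse a HomologyCall into the same category vocabulary as the
    truth-derived classifier above."""
    if call.relationship != "ortholog":
        return call.relationship
    if call.multiplicity in ("many-to-many", "many-to-one"):
        return call.multiplicity
    if call.multiplicity == "one-to-one":
        return "one-to-one"
    if call.multiplicity == "one-to-two":
        return "one-to-two"
    return "one-to-X"


def expected_duplications(species_root: Node, dup_rate: float) -> float:
    """Expected duplication-node count per family, loss-free.

    A lineage population of expected size N entering a branch of length t
    grows to N e^{λt} and produces N (e^{λt} - 1) duplications on the way;
    recurse over the species tree with one lineage entering each child of
    the root.
    """

    def walk(node: Node, n_in: float) -> float:
        growth = float(np.exp(dup_rate * node.length))
        dups = n_in * (growth - 1.0)
        n_out = n_in * growth
        for c in node.children:
            dups += walk(c, n_out)
        return dups

    return sum(walk(c, 1.0) for c in species_root.children)
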