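"""Tree model, Newick I/O, MRCA/distance/rooting/pruning primitives."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylograft.errors import NewickParseError, TreeError
from phylograft.tree import GeneTree, parse_newick, trees_equal, write_newick

from oracles import (
    brute_distances,
    brute_minimax_root_distance,
    brute_mrca,
    make_random_tree,
)


# ---------------------------------------------------------------------- parse


def test_parse_minimal_two_leaf_tree():
    t = parse_newick("(A:1,B:3);")
    assert sorted(t.leaf_labels()) == ["A", "B"]
    assert {lf.label: lf.length for lf in t.leaves()} == {"A": 1.0, "B": 3.0}


@pytest.mark.parametrize(
    "text",
    [
        "((A:1,B:1)90:2,C:4);",  # support as internal label
        "((A:1,B:1)[90]:2,C:4);",  # support as bracket comment, before length
        "((A:1,B:1):2[90],C:4);",  # support as bracket comment, after length
        "((A:1,B:1)[&support=90]:2,C:4);",  # annotated comment dialect
    ],
)
def test_parse_support_dialects(text):
    t = parse_newick(text)
    inner = next(n for n in t.internal_nodes() if n is not t.root)
    assert inner.support == 90.0
    assert inner.length == 2.0


def test_parse_absent_lengths_stay_absent_not_zero():
    t = parse_newick("((A,B),C);")
    assert all(lf.length is None for lf in t.leaves())


def test_parse_multifurcation_and_missing_semicolon():
    t = parse_newick("(A:1,B:1,C:1,D:1)")
    assert len(t.root.children) == 4


def test_parse_internal_label_above_100_is_a_name_not_support():
    t = parse_newick("((A:1,B:1)342:2,C:4);")
    inner = next(n for n in t.internal_nodes() if n is not t.root)
    assert inner.support is None and inner.label == "342"


@pytest.mark.parametrize(
    "bad, fragment",
    [
        ("((A:1,B:2);", "unbalanced"),
        ("(A:1,A:2);", "duplicate leaf label"),
        ("(A:-1,B:2);", "negative branch length"),
        ("(A:1,B:2);junk", "trailing"),
        ("", "empty"),
        ("(A:1,:2);", "leaf without a label"),
    ],
)
def test_parse_errors_name_the_position(bad, fragment):
    with pytest.raises(NewickParseError) as exc:
        parse_newick(bad)
    assert fragment in str(exc.value)
    assert "position" in str(exc.value)


# ---------------------------------------------------------------------- write


def test_write_without_lengths_has_no_colons():
    assert ":" not in write_newick(parse_newick("((A,B),C);"))


def test_write_round_trips_support_and_lengths():
    s = "((A:1,B:1)90:2,C:4);"
    assert trees_equal(parse_newick(s), parse_newick(write_newick(parse_newick(s))))


def test_roundtrip_on_simulated_trees(lossfree_families):
    for fam in lossfree_families[:100]:
        t = fam.gene_tree
        assert trees_equal(t, parse_newick(write_newick(t)), tol=1e-9)


# ----------------------------------------------------------------------- mrca


def test_mrca_trivial_cases():
    t = parse_newick("((A,B),C);")
    assert set(lf.label for lf in t.mrca({"A", "B"}).leaves()) == {"A", "B"}
    assert t.mrca({"A", "C"}) is t.root
    with pytest.raises(TreeError):
        t.mrca({"A", "Z"})


def test_mrca_matches_brute_force_on_random_trees(rng):
    for _ in range(10):
        t = make_random_tree(rng, 30)
        labels = t.leaf_labels()
        for _ in range(10):
            k = int(rng.integers(2, 6))
            query = set(rng.choice(labels, size=k, replace=False))
            assert t.mrca(query) is brute_mrca(t, query)


# ------------------------------------------------------------------ distances


def test_patristic_hand_examples():
    assert parse_newick("(A:1,B:3);").distance("A", "B") == 4.0
    assert parse_newick("((A:1,B:1):2,C:4);").distance("A", "C") == 7.0
    assert parse_newick("(A:1,B:3);").distance("A", "A") == 0.0


def test_patristic_missing_length_is_an_error_not_zero():
    t = parse_newick("((A:1,B),C:4);")
    with pytest.raises(TreeError, match="missing branch length"):
        t.distance("A", "B")


def test_patristic_matches_path_enumeration_oracle(rng):
    for _ in range(5):
        t = make_random_tree(rng, 25)
        oracle = brute_distances(t)
        for (a, b), d in oracle.items():
            assert t.distance(a, b) == pytest.approx(d, abs=1e-9)


def test_patristic_matches_dendropy(rng):
    t = make_random_tree(rng, 20)
    dt = dendropy.Tree.get(data=write_newick(t), schema="newick",
                           preserve_underscores=True)
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in dt.taxon_namespace}
    labels = t.leaf_labels()
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            assert t.distance(a, b) == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), abs=1e-9
            )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_patristic_is_a_metric(seed):
    rng = np.random.default_rng(seed)
    t = make_random_tree(rng, int(rng.integers(4, 15)))
    a, b, c = rng.choice(t.leaf_labels(), size=3, replace=False)
    dab, dbc, dac = t.distance(a, b), t.distance(b, c), t.distance(a, c)
    assert dab >= 0 and dab == t.distance(b, a)
    assert dac <= dab + dbc + 1e-9


# -------------------------------------------------------------------- rooting


def test_midpoint_two_leaf_tree():
    t = parse_newick("(A:1,B:3);").midpoint_root()
    assert t.distance("A", "B") == pytest.approx(4.0)
    depths = {lf.label: _depth(lf) for lf in t.leaves()}
    assert depths == {"A": pytest.approx(2.0), "B": pytest.approx(2.0)}


def _depth(leaf):
    d, n = 0.0, leaf
    while n.parent is not None:
        d += n.length
        n = n.parent
    return d


def test_midpoint_symmetric_tree_is_unchanged():
    s = "((A:1,B:1):1,(C:1,D:1):1);"
    t = parse_newick(s).midpoint_root()
    assert trees_equal(t, parse_newick(s))
    assert max(_depth(lf) for lf in t.leaves()) == pytest.approx(2.0)


def test_midpoint_requires_lengths_and_two_leaves():
    with pytest.raises(TreeError):
        parse_newick("((A,B),C);").midpoint_root()
    with pytest.raises(TreeError):
        parse_newick("A:1;").midpoint_root()


def test_midpoint_achieves_bruteforce_minimax_and_conserves_length(rng):
    for k in range(100):
        n = int(rng.integers(5, 51))
        t = make_random_tree(rng, n)
        rooted = t.midpoint_root()
        achieved = max(_depth(lf) for lf in rooted.leaves())
        assert achieved == pytest.approx(brute_minimax_root_distance(t), abs=1e-9)
        assert rooted.total_length() == pytest.approx(t.total_length(), abs=1e-9)
        assert sorted(rooted.leaf_labels()) == sorted(t.leaf_labels())


def test_midpoint_agrees_with_dendropy_minimax(rng):
    for _ in range(10):
        t = make_random_tree(rng, 20)
        dt = dendropy.Tree.get(data=write_newick(t), schema="newick",
                               preserve_underscores=True)
        dt.reroot_at_midpoint(update_bipartitions=False)
        ours = max(_depth(lf) for lf in t.midpoint_root().leaves())
        theirs = max(
            lf.distance_from_root() for lf in dt.leaf_node_iter()
        )
        assert ours == pytest.approx(theirs, abs=1e-6)


def test_midpoint_distances_are_rooting_invariant(rng):
    t = make_random_tree(rng, 15)
    rooted = t.midpoint_root()
    before = brute_distances(t)
    for (a, b), d in before.items():
        assert rooted.distance(a, b) == pytest.approx(d, abs=1e-9)


# -------------------------------------------------------------------- pruning


def test_prune_collapses_unary_nodes_and_sums_lengths(smap):
    t = parse_newick("((a_HSA:1,b_DRE:1):1,c_MZE:2);")
    pruned = t.prune_to_leaves(lambda lb: smap.resolve(lb) in {"HSA", "MZE"})
    assert trees_equal(pruned, parse_newick("(a_HSA:2,c_MZE:2);"))


def test_prune_keep_all_is_identity(smap):
    s = "((a_HSA:1,b_DRE:1):1,c_MZE:2);"
    t = parse_newick(s)
    assert trees_equal(t.prune_to_leaves(lambda lb: True), t)


def test_prune_empty_result_is_an_error(smap):
    t = parse_newick("(a_HSA:1,b_DRE:1);")
    with pytest.raises(TreeError, match="no retained leaves"):
        t.prune_to_leaves(lambda lb: False)


def test_prune_preserves_pairwise_distances(rng):
    for _ in range(10):
        t = make_random_tree(rng, 20)
        keep = set(rng.choice(t.leaf_labels(), size=8, replace=False))
        pruned = t.prune_to_leaves(lambda lb: lb in keep)
        assert set(pruned.leaf_labels()) == keep
        assert not any(
            len(n.children) == 1 for n in pruned.nodes()
        ), "prune must leave no unary nodes"
        for a in keep:
            for b in keep:
                assert pruned.distance(a, b) == pytest.approx(t.distance(a, b), abs=1e-9)
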