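"""Dollo-parsimony reconstruction against a brute-force enumeration oracle."""

from __future__ import annotations

import random

import dendropy
import pytest

from intronevol.dollo import (
    DolloError,
    ROOT_AMBIGUOUS,
    infer_site,
    reconstruct,
    summarize,
    genes_with_both,
)
from intronevol.homology import IntronSite
from intronevol.io_formats import tree_from_string
from oracles import dollo_min_losses, maximal_absent_subtrees


def _tree(newick: str):
    return tree_from_string(newick)


def random_rooted_tree(n_leaves: int, rng: random.Random) -> str:
    """Random rooted binary topology by sequential joining."""
    nodes = [f"L{i}:1" for i in range(n_leaves)]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b}):1")
    return nodes[0].rsplit(":", 1)[0] + ";"


def test_single_clade_gain_no_losses():
    tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
    gain, losses = infer_site({"A": True, "B": True, "C": False, "D": False}, tree)
    assert gain != ROOT_AMBIGUOUS
    clade = {
        lf.taxon.label
        for n in tree.preorder_node_iter() if n.label == gain
        for lf in n.leaf_iter()
    }
    assert clade == {"A", "B"}
    assert losses == []


def test_straddling_presence_is_root_ambiguous():
    tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
    gain, losses = infer_site({"A": True, "B": False, "C": True, "D": False}, tree)
    assert gain == ROOT_AMBIGUOUS
    # losses below the root are still reconstructed: B and D each lost it
    lost_leaves = set()
    for label in losses:
        node = next(n for n in tree.preorder_node_iter() if n.label == label)
        lost_leaves |= {lf.taxon.label for lf in node.leaf_iter()}
    assert lost_leaves == {"B", "D"}


def test_all_absent_vector_is_error():
    tree = _tree("((A:1,B:1):1,C:1);")
    with pytest.raises(DolloError, match="all-absent"):
        infer_site({"A": False, "B": False, "C": False}, tree)


def test_incomplete_vector_is_error():
    tree = _tree("((A:1,B:1):1,C:1);")
    with pytest.raises(DolloError, match="incomplete"):
        infer_site({"A": True, "B": True}, tree)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_loss_count_matches_bruteforce_minimum(seed):
    """On random trees, the reconstruction attains the exhaustive minimum
    loss count over all single-gain placements, for every presence pattern."""
    rng = random.Random(seed)
    for _ in range(5):
        n = rng.randint(3, 6)
        tree = _tree(random_rooted_tree(n, rng))
        leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        for mask in range(1, 2 ** n):
            presence = {sp: bool(mask >> i & 1) for i, sp in enumerate(leaves)}
            _, losses = infer_site(presence, tree)
            present = {sp for sp, p in presence.items() if p}
            assert len(losses) == dollo_min_losses(tree, present)


def test_losses_are_maximal_absent_subtrees():
    rng = random.Random(99)
    tree = _tree(random_rooted_tree(6, rng))
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    for mask in (0b000111, 0b101010, 0b110001):
        presence = {sp: bool(mask >> i & 1) for i, sp in enumerate(leaves)}
        gain, losses = infer_site(presence, tree)
        present = {sp for sp, p in presence.items() if p}
        node = (
            tree.seed_node
            if gain == ROOT_AMBIGUOUS
            else next(n for n in tree.preorder_node_iter() if n.label == gain)
        )
        assert set(losses) == maximal_absent_subtrees(node, present)


def test_leaf_relabeling_permutes_but_preserves_event_counts():
    tree1 = _tree("((A:1,B:2):1,(C:3,D:1):2);")
    tree2 = _tree("((D:1,C:2):1,(B:3,A:1):2);")
    presence = {"A": True, "B": True, "C": False, "D": True}
    swapped = {"D": True, "C": True, "B": False, "A": True}
    g1, l1 = infer_site(presence, tree1)
    g2, l2 = infer_site(swapped, tree2)
    assert (g1 == ROOT_AMBIGUOUS) == (g2 == ROOT_AMBIGUOUS)
    assert len(l1) == len(l2)


def _site(group, presence):
    return IntronSite(group_id=group, column=0, phase=0, presence=presence)


def test_summarize_rate_arithmetic():
    """10 gains over 1,000 genes on a 10 My branch = 1.0 gains/gene/Bya."""
    tree = _tree("((A:10,B:10):10,C:20);")
    sites = [
        _site(f"g{i}", {"A": True, "B": False, "C": False}) for i in range(10)
    ]
    recon = reconstruct(sites, tree)
    rates = summarize(recon, n_genes=1000)
    row = rates.set_index("branch").loc["A"]
    assert row["n_gains"] == 10
    assert row["gain_rate"] == pytest.approx(1.0)
    total = rates.set_index("branch").loc["TOTAL"]
    assert total["n_gains"] == 10 and total["n_losses"] == 0


def test_summarize_zero_gains_zero_rates():
    tree = _tree("((A:10,B:10):10,C:20);")
    sites = [_site("g0", {"A": True, "B": True, "C": True})]
    recon = reconstruct(sites, tree)
    rates = summarize(recon, n_genes=100)
    assert (rates["gain_rate"] == 0).all()
    assert rates.attrs["n_root_ambiguous"] == 1


def test_genes_with_both_requires_gain_and_loss():
    tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
    sites = [
        # gainonly: one novel site, no losses
        _site("gainonly", {"A": True, "B": True, "C": False, "D": False}),
        # both: an ancestral site lost in one leaf plus a novel site
        _site("both", {"A": True, "B": True, "C": True, "D": False}),
        _site("both", {"A": True, "B": True, "C": False, "D": False}),
        # lossonly: ancestral site with one loss
        _site("lossonly", {"A": False, "B": True, "C": True, "D": True}),
    ]
    recon = reconstruct(sites, tree)
    assert genes_with_both(recon) == ["both"]
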