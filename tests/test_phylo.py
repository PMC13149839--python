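"""Neighbour joining, distance models, bootstrap supports."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from codtr.phylo import (
    k2p_distance_matrix,
    neighbor_joining,
    nj_tree,
    p_distance_matrix,
)


def test_nj_exact_on_additive_four_taxon_matrix():
    names = ["a", "b", "c", "d"]
    # tree: (a:2,b:3) -3- (c:4,d:3)
    dist = np.array(
        [[0, 5, 9, 10], [5, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
    )
    tree = neighbor_joining(names, dist)
    for x, y in itertools.combinations(range(4), 2):
        patristic = tree.find(names[x]).distance(tree.find(names[y]))
        assert patristic == pytest.approx(dist[x, y])
    # topology: a-b form a cherry
    a = tree.find("a")
    assert {t.name for t in a.parent.tips()} == {"a", "b"}


def test_nj_topology_matches_reference_implementation():
    rng = np.random.default_rng(51)
    names = list("abcdefg")
    # random additive tree distances via random positive branch mix
    coords = rng.random((7, 5))
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(dist, 0)
    ours = neighbor_joining(names, dist)
    ref = skbio_nj(DistanceMatrix(dist, names))

    def bipartitions(tree):
        taxa = frozenset(names)
        parts = set()
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if min(taxa) in side:
                side = taxa - side
            if 2 <= len(side) <= len(taxa) - 2:
                parts.add(side)
        return parts

    assert bipartitions(ours) == bipartitions(ref)


def test_identical_sequences_have_zero_distances():
    aln = [(f"t{i}", "ACGTACGTAC") for i in range(4)]
    _, dist = p_distance_matrix(aln)
    assert np.allclose(dist, 0)


def test_p_distance_matches_hand_count_with_pairwise_deletion():
    aln = [
        ("a", "ACGT-CGTAN"),
        ("b", "ACGTACGTAA"),
        ("c", "TCGAACGAAA"),
        ("d", "ACGTACGTAC"),
        ("e", "ANGTACGTAC"),
    ]
    names, dist = p_distance_matrix(aln)

    def oracle(x, y):
        usable = mism = 0
        for cx, cy in zip(x, y):
            if cx in "-N" or cy in "-N":
                continue
            usable += 1
            mism += cx != cy
        return mism / usable

    seqs = dict(aln)
    for i, j in itertools.combinations(range(5), 2):
        assert dist[i, j] == pytest.approx(oracle(seqs[names[i]], seqs[names[j]]))


def test_k2p_formula_and_gamma_variant():
    # 100 sites: 10 transitions (A<->G), 5 transversions (A<->C)
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    aln = [("a", a), ("b", b), ("c", a)]
    _, dist = k2p_distance_matrix(aln)
    P, Q = 0.10, 0.05
    expected = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
    assert dist[0, 1] == pytest.approx(expected)
    shape = 5.0
    _, gdist = k2p_distance_matrix(aln, gamma_shape=shape)
    gexp = (shape / 2) * ((1 - 2 * P - Q) ** (-1 / shape) - 1) + (shape / 4) * (
        (1 - 2 * Q) ** (-1 / shape) - 1
    )
    assert gdist[0, 1] == pytest.approx(gexp)


def test_k2p_saturation_error_names_the_pair():
    aln = [("sat1", "ACACACAC"), ("sat2", "GTGTGTGT"), ("c", "ACACACAC")]
    with pytest.raises(ValueError, match="sat1.*sat2"):
        k2p_distance_matrix(aln)


def test_bootstrap_on_unambiguous_alignment_is_100():
    # every column carries the same split signal, so all replicates agree
    col = {"a": "A", "b": "A", "c": "T", "d": "T", "e": "G", "f": "G"}
    aln = [(n, c * 30) for n, c in col.items()]
    tree = nj_tree(aln, n_bootstrap=50, seed=0)
    supports = [
        node.bootstrap_support
        for node in tree.non_tips(include_self=False)
        if hasattr(node, "bootstrap_support")
    ]
    assert supports and all(s == 100.0 for s in supports)


def test_nj_tree_deterministic_given_seed():
    rng = np.random.default_rng(52)
    aln = [
        (f"t{i}", "".join(rng.choice(list("ACGT"), size=60))) for i in range(5)
    ]
    t1 = nj_tree(aln, n_bootstrap=25, seed=7)
    t2 = nj_tree(aln, n_bootstrap=25, seed=7)
    assert str(t1) == str(t2)


def test_too_few_taxa_rejected():
    with pytest.raises(ValueError):
        nj_tree([("a", "AC"), ("b", "AC")])
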