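"""Subgroup clustering, translocon delineation, mini-cluster grouping."""

import numpy as np
import pytest

from codtr.grouping import (
    cluster_subgroups,
    delineate_translocons,
    group_miniclusters,
    pairwise_identity,
)
from codtr.model import GeneSegment, GenomicSequence, LocusMap
from codtr.simlocus import _back_translate, _rand_protein


def _locus_of_types(spec):
    """Build a LocusMap from [(segment_type, strand), ...] with spaced
    dummy coordinates."""
    segs = [
        GeneSegment(t, "g", [(100 * i, 100 * i + 50)], strand)
        for i, (t, strand) in enumerate(spec)
    ]
    return LocusMap(contig="g", segments=segs)


def _v_locus_from_proteins(proteins, rng):
    parts, segs, pos = [], [], 0
    for prot in proteins:
        nt = _back_translate(prot, rng)
        segs.append(GeneSegment("V", "g", [(pos, pos + len(nt))], "+"))
        parts.append(nt)
        pos += len(nt)
    return GenomicSequence("g", "".join(parts)), segs


def _mutated(prot, rng, n):
    out = list(prot)
    sites = rng.choice(np.arange(len(prot)), size=n, replace=False)
    for p in sites:
        out[p] = "G" if out[p] != "G" else "A"
    return "".join(out)


def test_identical_sequences_share_a_subgroup():
    rng = np.random.default_rng(41)
    prot = _rand_protein(rng, 60)
    genome, segs = _v_locus_from_proteins([prot, prot], rng)
    cluster_subgroups(segs, genome)
    assert segs[0].subgroup == segs[1].subgroup == 1


def test_85_percent_identity_pair_clusters_together():
    rng = np.random.default_rng(42)
    prot = _rand_protein(rng, 100)
    pair = [prot, _mutated(prot, rng, 15)]
    assert pairwise_identity(pair[0], pair[1]) == pytest.approx(0.85)
    genome, segs = _v_locus_from_proteins(pair, rng)
    cluster_subgroups(segs, genome, threshold=0.80)
    assert segs[0].subgroup == segs[1].subgroup


def test_70_percent_identity_pair_separates():
    rng = np.random.default_rng(43)
    prot = _rand_protein(rng, 100)
    pair = [prot, _mutated(prot, rng, 30)]
    genome, segs = _v_locus_from_proteins(pair, rng)
    cluster_subgroups(segs, genome, threshold=0.80)
    assert segs[0].subgroup != segs[1].subgroup


def test_permutation_invariance_and_threshold_monotonicity():
    rng = np.random.default_rng(44)
    founders = [_rand_protein(rng, 80) for _ in range(3)]
    proteins = [m for f in founders for m in (f, _mutated(f, rng, 6), _mutated(f, rng, 8))]

    def partition(order, threshold):
        genome, segs = _v_locus_from_proteins([proteins[i] for i in order], rng)
        cluster_subgroups(segs, genome, threshold=threshold)
        labels = {}
        for pos, i in enumerate(order):
            labels[i] = segs[pos].subgroup
        groups = {}
        for i, lab in labels.items():
            groups.setdefault(lab, frozenset())
            groups[lab] = groups[lab] | {i}
        return frozenset(groups.values())

    base = partition(list(range(9)), 0.80)
    shuffled = list(range(9))
    np.random.default_rng(1).shuffle(shuffled)
    assert partition(shuffled, 0.80) == base

    loose = partition(list(range(9)), 0.70)
    tight = partition(list(range(9)), 0.90)
    # every tight cluster is contained in some loose cluster (refinement)
    for t in tight:
        assert any(t <= l for l in loose)


def test_translocon_delineation_three_runs():
    spec = []
    for _ in range(3):
        spec += [("V", "+")] * 2 + [("D", "+"), ("J", "+"), ("C", "+")]
    locus = _locus_of_types(spec)
    delineate_translocons(locus)
    assert [t for t, _ in locus.translocons] == [1, 2, 3]
    groups = [s.group_id for s in locus.segments]
    assert groups == [1] * 5 + [2] * 5 + [3] * 5


def test_single_run_is_one_translocon():
    locus = _locus_of_types([("V", "+"), ("J", "+"), ("C", "+")])
    delineate_translocons(locus)
    assert len(locus.translocons) == 1
    assert all(s.group_id == 1 for s in locus.segments)


def test_c_preceding_all_v_flagged_unassignable():
    locus = _locus_of_types([("C", "+"), ("V", "+"), ("J", "+"), ("C", "+")])
    delineate_translocons(locus)
    assert locus.segments[0].group_id is None
    assert all(s.group_id == 1 for s in locus.segments[1:])


def test_minicluster_grouping_with_partial_reverse_cluster():
    spec = [("V", "+"), ("J", "+"), ("C", "+")] * 6 + [("J", "-"), ("V", "-")]
    locus = _locus_of_types(spec)
    group_miniclusters(locus)
    completes = [c for _, _, c in locus.miniclusters]
    assert completes == [True] * 6 + [False]
    assert locus.segments[-1].group_id == 7 and locus.segments[-2].group_id == 7


def test_minicluster_missing_j_is_partial():
    locus = _locus_of_types([("V", "+"), ("C", "+")])
    group_miniclusters(locus)
    assert locus.miniclusters == [(1, [None, None], False)]


def test_empty_locus_has_no_clusters():
    locus = LocusMap(contig="g", segments=[])
    group_miniclusters(locus)
    assert locus.miniclusters == []
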