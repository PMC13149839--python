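"""Subgroup clustering and locus-level grouping of gene segments.

V subgroups are single-linkage clusters of translated V exons at >80%
pairwise amino-acid identity (matches over aligned positions, with gap
and ambiguous columns deleted pairwise).  Translocons are maximal
V-run..C runs of a beta-type locus; mini-clusters are the compact
V-J-C repeat units of a gamma-type locus.
"""

from __future__ import annotations

import itertools
import logging

from Bio.Align import PairwiseAligner, substitution_matrices

from .functionality import translate_frame
from .model import GeneSegment, GenomicSequence, LocusMap

log = logging.getLogger(__name__)

_AMBIGUOUS_AA = set("X*?")


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Fraction of matching residues over aligned, unambiguous columns."""
    if not a or not b:
        return 0.0
    aligner = aligner or _identity_aligner()
    best = aligner.align(a, b)[0]
    sa, sb = str(best[0]), str(best[1])
    matches = usable = 0
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-" or ca in _AMBIGUOUS_AA or cb in _AMBIGUOUS_AA:
            continue
        usable += 1
        matches += ca == cb
    return matches / usable if usable else 0.0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_subgroups(
    v_segments: list[GeneSegment],
    genome: GenomicSequence,
    threshold: float = 0.80,
) -> list[GeneSegment]:
    """Assign subgroup labels (positive ints, ordered by 5'-most member).

    Two V genes whose translated exons exceed ``threshold`` identity end
    up in the same subgroup (single linkage, so subgroup membership is
    transitive).  Untranslatable segments are skipped with a warning.
    """
    if not v_segments:
        raise ValueError("need at least one V segment")
    usable: list[GeneSegment] = []
    proteins: list[str] = []
    for seg in v_segments:
        aa = translate_frame(seg.coding_sequence(genome), 0)
        if not aa:
            log.warning("skipping untranslatable V segment at %s", seg.start)
            seg.subgroup = None
            continue
        usable.append(seg)
        proteins.append(aa)
    uf = _UnionFind(len(usable))
    aligner = _identity_aligner()
    for i, j in itertools.combinations(range(len(usable)), 2):
        if pairwise_identity(proteins[i], proteins[j], aligner) > threshold:
            uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(usable)):
        clusters.setdefault(uf.find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda idx: min(usable[i].start for i in idx))
    for label, members in enumerate(ordered, start=1):
        for i in members:
            usable[i].subgroup = label
    return v_segments


def delineate_translocons(locus: LocusMap) -> LocusMap:
    """Assign translocon indices to a V..C translocon-organised locus.

    Each maximal run starting at the 5'-most V gene after the previous
    translocon's C gene forms one translocon, numbered 5'->3' from 1;
    every segment up to the last segment before the next V run belongs
    to it.  Segments preceding the first V gene are flagged unassignable.
    """
    segs = locus.segments
    v_idx = [i for i, s in enumerate(segs) if s.segment_type == "V"]
    if not v_idx:
        raise ValueError("locus contains no V genes")
    # starts of V runs: a V whose preceding segment block contains a C
    run_starts = [v_idx[0]]
    for i in v_idx[1:]:
        between = segs[run_starts[-1] : i]
        if any(s.segment_type == "C" for s in between):
            if segs[i - 1].segment_type != "V":
                run_starts.append(i)
    unassigned = segs[: run_starts[0]]
    for s in unassigned:
        s.group_id = None
        log.warning(
            "segment at %d precedes the first V gene; translocon unassignable",
            s.start,
        )
    translocons: list[tuple[int, tuple[int, int]]] = []
    bounds = run_starts + [len(segs)]
    for t, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
        members = segs[lo:hi]
        for s in members:
            s.group_id = t
        translocons.append((t, (members[0].start, members[-1].end)))
    locus.translocons = translocons
    return locus


def group_miniclusters(locus: LocusMap) -> LocusMap:
    """Assign mini-cluster indices and completeness flags (gamma loci).

    Each V gene seeds a cluster; forward-strand J/C genes join the
    nearest V on their left, reverse-strand ones the nearest V on their
    right (following transcription direction).  A cluster is complete
    when it holds a V, a J and a C on one strand.
    """
    segs = locus.segments
    v_positions = [(i, s) for i, s in enumerate(segs) if s.segment_type == "V"]
    locus.miniclusters = []
    if not v_positions:
        return locus
    assignment: dict[int, list[GeneSegment]] = {i: [s] for i, s in v_positions}
    for i, s in enumerate(segs):
        if s.segment_type == "V":
            continue
        host = None
        if s.strand == "+":
            lefts = [(vi, vs) for vi, vs in v_positions if vi < i and vs.strand == "+"]
            if lefts:
                host = lefts[-1][0]
        else:
            rights = [(vi, vs) for vi, vs in v_positions if vi > i and vs.strand == "-"]
            if rights:
                host = rights[0][0]
        if host is None:
            log.warning("segment at %d not assignable to any mini-cluster", s.start)
            s.group_id = None
            continue
        assignment[host].append(s)
    for number, vi in enumerate(sorted(assignment, key=lambda i: segs[i].start), 1):
        members = assignment[vi]
        types = {m.segment_type for m in members}
        complete = {"V", "J", "C"} <= types
        for m in members:
            m.group_id = number
        locus.miniclusters.append(
            (number, [m.name for m in members], complete)
        )
    return locus
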