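"""End-to-end germline TR locus annotation.

Pipeline: six-frame homology scan for V and C genes, RSS motif scan,
RSS attachment (V/J), D detection from facing RSS pairs, J gene
delineation from 12-spacer RSSs plus the F/W-G-X-G anchor,
functionality classification, subgroup clustering, translocon or
mini-cluster grouping, and nomenclature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .functionality import FunctionalityConfig, classify_functionality, find_j_anchor
from .grouping import cluster_subgroups, delineate_translocons, group_miniclusters
from .homology import CodingCandidate, find_coding_candidates
from .model import GeneSegment, GenomicSequence, LocusMap, ReferenceProtein, revcomp
from .naming import NamingConfig, assign_names
from .rss import RssConfig, attach_rss, detect_d_segments, scan_rss

log = logging.getLogger(__name__)

#: nt between the J anchor's F/W codon start and the end of the G-X-G codons
_ANCHOR_SPAN = 12


@dataclass
class AnnotateConfig:
    rss: RssConfig = field(default_factory=RssConfig)
    functionality: FunctionalityConfig = field(default_factory=FunctionalityConfig)
    naming: NamingConfig = field(default_factory=NamingConfig)
    min_score: float = 100.0
    max_gap: int = 10
    subgroup_threshold: float = 0.80
    max_d_length: int = 40
    j_window: int = 80
    j_tail: int = 6


def _drafts_from_candidates(
    candidates: list[CodingCandidate], contig: str
) -> list[GeneSegment]:
    drafts = []
    for cand in candidates:
        drafts.append(
            GeneSegment(
                segment_type=cand.ref.ptype,
                contig=contig,
                coding_intervals=[cand.interval],
                strand=cand.strand,
                frame=0,
                chain=cand.ref.chain,
                score=cand.score,
                ref_id=cand.ref.id,
            )
        )
    return drafts


def _extend_v_to_rss(seg: GeneSegment) -> None:
    """Extend a V coding interval to the heptamer of its attached RSS,
    covering the partial-codon CDR3 opening after the 2nd-CYS."""
    if not seg.rss:
        return
    motif = seg.rss[0]
    start, end = seg.coding_intervals[-1]
    if seg.strand == "+":
        seg.coding_intervals[-1] = (start, motif.start)
    else:
        s0, _ = seg.coding_intervals[0]
        seg.coding_intervals[0] = (motif.end, seg.coding_intervals[0][1])
        if len(seg.coding_intervals) == 1:
            seg.coding_intervals[0] = (motif.end, end)


def _build_j_drafts(
    genome: GenomicSequence,
    rss_hits,
    config: AnnotateConfig,
    exclude,
) -> list[GeneSegment]:
    """Delineate J genes next to 12-spacer RSSs.

    The J coding region runs from the heptamer edge to the end of the
    first F/W-G-X-G anchor (earliest in any frame) plus a short fixed
    tail; its frame is the anchor's frame.
    """
    drafts = []
    for motif in rss_hits:
        if motif.spacer_length not in config.rss.j_spacers or motif in exclude:
            continue
        if motif.strand == "-":
            start = motif.end
            window = genome.residues[start : start + config.j_window]
            strand = "+"
        else:
            end = motif.start
            window = revcomp(genome.residues[max(0, end - config.j_window) : end])
            strand = "-"
        anchors = [a for a in (find_j_anchor(window, f) for f in range(3)) if a is not None]
        if not anchors:
            continue
        anchor = min(anchors)
        j_len = anchor + _ANCHOR_SPAN + config.j_tail
        if j_len > len(window):
            continue
        if motif.strand == "-":
            interval = (motif.end, motif.end + j_len)
        else:
            interval = (motif.start - j_len, motif.start)
        drafts.append(
            GeneSegment(
                segment_type="J",
                contig=genome.id,
                coding_intervals=[interval],
                strand=strand,
                frame=anchor % 3,
                rss=[motif],
            )
        )
    return drafts


def _assign_jd_chains(segments: list[GeneSegment]) -> None:
    """J and D genes inherit the chain of their constant gene: the
    nearest C downstream in transcription direction (genomic right for
    forward genes, left for reverse genes)."""
    c_segs = [s for s in segments if s.segment_type == "C"]
    if not c_segs:
        return
    for seg in segments:
        if seg.segment_type not in "JD" or seg.chain is not None:
            continue
        if seg.strand == "+":
            side = [c for c in c_segs if c.start >= seg.end]
            pick = min(side, key=lambda c: c.start) if side else None
        else:
            side = [c for c in c_segs if c.end <= seg.start]
            pick = max(side, key=lambda c: c.end) if side else None
        if pick is None:
            pick = min(c_segs, key=lambda c: abs(c.start - seg.start))
        seg.chain = pick.chain


def _overlaps_any(seg: GeneSegment, others: list[GeneSegment]) -> bool:
    return any(seg.start < o.end and o.start < seg.end for o in others)


def annotate_genome(
    genome: GenomicSequence,
    refs: list[ReferenceProtein],
    config: AnnotateConfig | None = None,
) -> LocusMap:
    """Annotate one contig and return its LocusMap."""
    config = config or AnnotateConfig()
    rss_hits = scan_rss(genome, config.rss)
    candidates = find_coding_candidates(genome, refs, config.min_score)
    vc_drafts = _drafts_from_candidates(candidates, genome.id)
    v_drafts = [d for d in vc_drafts if d.segment_type == "V"]
    c_drafts = [d for d in vc_drafts if d.segment_type == "C"]
    attach_rss(v_drafts, rss_hits, config.max_gap, config.rss)
    for seg in v_drafts:
        _extend_v_to_rss(seg)

    used = {m for seg in v_drafts for m in seg.rss}
    d_drafts = [
        d
        for d in detect_d_segments(
            rss_hits, genome.id, config.max_d_length, config=config.rss
        )
        if not _overlaps_any(d, v_drafts + c_drafts)
        and not (set(d.rss) & used)
    ]
    used |= {m for seg in d_drafts for m in seg.rss}
    j_drafts = _build_j_drafts(genome, rss_hits, config, used)
    j_drafts = [j for j in j_drafts if not _overlaps_any(j, v_drafts + c_drafts + d_drafts)]
    attach_rss(j_drafts, rss_hits, config.max_gap, config.rss)

    segments = v_drafts + c_drafts + d_drafts + j_drafts
    for seg in segments:
        classify_functionality(seg, genome, config.functionality)
    _assign_jd_chains(segments)

    locus = LocusMap(contig=genome.id, segments=segments)
    chains = {s.chain for s in locus.segments if s.chain}
    if "B" in chains:
        scheme = "B"
    elif "G" in chains:
        scheme = "G"
    else:
        scheme = "A/D"

    v_segs = locus.by_type("V")
    if v_segs:
        cluster_subgroups(v_segs, genome, config.subgroup_threshold)
    if scheme in ("B", "A/D"):
        delineate_translocons(locus)
    else:
        group_miniclusters(locus)
    assign_names(locus, scheme, config.naming)
    if scheme == "G":
        from .naming import refresh_minicluster_names

        refresh_minicluster_names(locus)
    for seg in locus.segments:
        seg.validate()
    return locus
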