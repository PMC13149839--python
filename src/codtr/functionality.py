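"""Gene-segment functionality classification.

A V gene is functional when its coding region translates without an
internal stop, carries an attached RSS, and its 3' end encodes the
conserved 2nd-CYS (Cys104) in the reading frame of the gene, opening
into the CDR3.  A J gene is functional when it carries an RSS, the
canonical F/W-G-X-G anchor motif in its reading frame, and no stop
codon upstream of the anchor.  All failed checks accumulate as defect
reasons; any defect makes the segment a pseudogene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .model import GeneSegment, GenomicSequence

#: J anchor: Phe/Trp followed by Gly-X-Gly
J_ANCHOR_RE = re.compile(r"[FW]G.G")

#: terminal window (in codons) searched for the 2nd-CYS
CYS_WINDOW = 4


@dataclass
class FunctionalityConfig:
    cys_window: int = CYS_WINDOW
    require_j_motif: bool = True


def translate_frame(nt: str, frame: int = 0) -> str:
    """Translate complete codons of ``nt`` starting at ``frame``."""
    usable = (len(nt) - frame) // 3 * 3
    if usable <= 0:
        return ""
    return str(Seq(nt[frame : frame + usable]).translate())


def find_j_anchor(nt: str, frame: int) -> int | None:
    """Position (nt offset) of the F/W-G-X-G anchor in ``frame``, or None."""
    aa = translate_frame(nt, frame)
    m = J_ANCHOR_RE.search(aa)
    if m is None:
        return None
    return frame + 3 * m.start()


def _classify_v(seg: GeneSegment, nt: str, config: FunctionalityConfig) -> list[str]:
    reasons = list(seg.defect_reasons)
    aa = translate_frame(nt, 0)
    window = aa[-config.cys_window :]
    cys_in_frame = "C" in window
    # a register shift places the terminal Cys in a shifted frame instead
    shifted_cys = any(
        "C" in translate_frame(nt, f)[-config.cys_window :] for f in (1, 2)
    )
    if cys_in_frame:
        cys_aa_pos = len(aa) - config.cys_window + window.rindex("C")
        if "*" in aa[:cys_aa_pos]:
            reasons.append("stop_codon")
    else:
        if shifted_cys:
            reasons.append("frameshift")
        else:
            reasons.append("missing_cys104")
            reasons.append("incomplete_cdr3")
        if "*" in aa[:-1]:
            reasons.append("stop_codon")
    if not seg.rss:
        reasons.append("missing_rss")
    return reasons


def _classify_j(seg: GeneSegment, nt: str, config: FunctionalityConfig) -> list[str]:
    reasons = list(seg.defect_reasons)
    if not seg.rss:
        reasons.append("missing_rss")
    anchor = find_j_anchor(nt, seg.frame)
    if anchor is None:
        if config.require_j_motif:
            reasons.append("incomplete_cdr3")
        if "*" in translate_frame(nt, seg.frame)[:-1]:
            reasons.append("stop_codon")
    else:
        aa_upstream = translate_frame(nt, seg.frame)[: (anchor - seg.frame) // 3]
        if "*" in aa_upstream:
            reasons.append("stop_codon")
    return reasons


def classify_functionality(
    segment: GeneSegment,
    genome: GenomicSequence,
    config: FunctionalityConfig | None = None,
) -> GeneSegment:
    """Set ``functionality`` and ``defect_reasons`` on ``segment`` in place."""
    config = config or FunctionalityConfig()
    if not segment.coding_intervals:
        raise ValueError("segment has no coding interval")
    nt = segment.coding_sequence(genome)
    if segment.segment_type == "V":
        reasons = _classify_v(segment, nt, config)
    elif segment.segment_type == "J":
        reasons = _classify_j(segment, nt, config)
    elif segment.segment_type == "D":
        reasons = list(segment.defect_reasons)
        if len(segment.rss) != 2 or segment.rss[0].strand == segment.rss[1].strand:
            reasons.append("missing_rss")
    else:  # C genes carry no RSS; require an open reading frame only
        reasons = list(segment.defect_reasons)
        aa = translate_frame(nt, segment.frame)
        if "*" in aa[:-1]:
            reasons.append("stop_codon")
    segment.defect_reasons = list(dict.fromkeys(reasons))
    segment.functionality = "pseudogene" if segment.defect_reasons else "functional"
    return segment
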