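"""Recombination signal sequence (RSS) scanning and segment/RSS pairing.

An RSS is a conserved heptamer (canonical CACAGTG) and nonamer (canonical
ACAAAAACC) separated by a 12- or 22/23-bp spacer.  The scanner reports
every motif on both strands within a configurable mismatch budget; the
first three heptamer bases (CAC), which are critical for cleavage, can be
required to match exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    CANONICAL_HEPTAMER,
    CANONICAL_NONAMER,
    GeneSegment,
    GenomicSequence,
    RssMotif,
    revcomp,
)

log = logging.getLogger(__name__)


@dataclass
class RssConfig:
    """Mismatch budgets and spacer sets for the RSS scan.

    Defaults allow one heptamer and two nonamer substitutions (with the
    CAC core fixed), which is enough to pick up the ACATAAACC nonamer
    variant while keeping the chance-hit rate per genome low.
    """

    spacer_lengths: tuple[int, ...] = (12, 22, 23)
    max_heptamer_mismatches: int = 1
    max_nonamer_mismatches: int = 2
    require_cac: bool = True
    # spacer sets accepted when pairing an RSS with a segment type
    v_spacers: tuple[int, ...] = (22, 23)
    j_spacers: tuple[int, ...] = (12,)
    d_spacers_short: tuple[int, ...] = (12,)
    d_spacers_long: tuple[int, ...] = (22, 23)

    def __post_init__(self) -> None:
        if not self.spacer_lengths:
            raise ValueError("spacer length set must be non-empty")
        if self.max_heptamer_mismatches < 0 or self.max_nonamer_mismatches < 0:
            raise ValueError("mismatch maxima must be >= 0")


def _mismatch_profile(seq_arr: np.ndarray, motif: str) -> np.ndarray:
    """mism[p] = Hamming distance between seq[p:p+len(motif)] and motif."""
    n, k = len(seq_arr), len(motif)
    if n < k:
        return np.empty(0, dtype=np.int32)
    out = np.zeros(n - k + 1, dtype=np.int32)
    motif_b = np.frombuffer(motif.encode(), dtype=np.uint8)
    for i in range(k):
        out += seq_arr[i : n - k + 1 + i] != motif_b[i]
    return out


def _scan_one_strand(residues: str, config: RssConfig) -> list[tuple[int, int, int, int]]:
    """Forward-strand motif scan: (start, spacer, hept_mm, non_mm) tuples."""
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    hept_mm = _mismatch_profile(arr, CANONICAL_HEPTAMER)
    non_mm = _mismatch_profile(arr, CANONICAL_NONAMER)
    if config.require_cac:
        cac_ok = _mismatch_profile(arr, "CAC") == 0
    hits = []
    for spacer in sorted(set(config.spacer_lengths)):
        span = 7 + spacer + 9
        if len(arr) < span:
            continue
        limit = len(arr) - span + 1
        h = hept_mm[:limit]
        n9 = non_mm[7 + spacer : 7 + spacer + limit]
        ok = (h <= config.max_heptamer_mismatches) & (
            n9 <= config.max_nonamer_mismatches
        )
        if config.require_cac:
            ok &= cac_ok[:limit]
        for p in np.flatnonzero(ok):
            hits.append((int(p), spacer, int(h[p]), int(n9[p])))
    return hits


def scan_rss(genome: GenomicSequence, config: RssConfig | None = None) -> list[RssMotif]:
    """Find all RSS motifs on both strands of ``genome``.

    Returns hits sorted by (start, strand).  Scanning the reverse
    complement of the genome yields the coordinate-mirrored hit set.
    """
    config = config or RssConfig()
    n = len(genome)
    motifs: list[RssMotif] = []
    for p, spacer, hm, nm in _scan_one_strand(genome.residues, config):
        span = 7 + spacer + 9
        motifs.append(
            RssMotif(
                heptamer_seq=genome.residues[p : p + 7],
                nonamer_seq=genome.residues[p + 7 + spacer : p + span],
                spacer_length=spacer,
                heptamer_mismatches=hm,
                nonamer_mismatches=nm,
                start=p,
                end=p + span,
                strand="+",
            )
        )
    rc = revcomp(genome.residues)
    for p, spacer, hm, nm in _scan_one_strand(rc, config):
        span = 7 + spacer + 9
        motifs.append(
            RssMotif(
                heptamer_seq=rc[p : p + 7],
                nonamer_seq=rc[p + 7 + spacer : p + span],
                spacer_length=spacer,
                heptamer_mismatches=hm,
                nonamer_mismatches=nm,
                start=n - (p + span),
                end=n - p,
                strand="-",
            )
        )
    motifs.sort(key=lambda m: (m.start, m.strand, m.spacer_length))
    return motifs


def _edge_gap(segment: GeneSegment, motif: RssMotif) -> int | None:
    """Gap in nt between a segment's recombining edge and a motif's
    heptamer, or None when the motif faces the wrong way."""
    edge = segment.recombining_edge
    coding_on_left = (
        (segment.segment_type == "V" and segment.strand == "+")
        or (segment.segment_type == "J" and segment.strand == "-")
    )
    if coding_on_left:
        # motif must sit to the right of the edge, heptamer first
        if motif.strand != "+":
            return None
        gap = motif.start - edge
    else:
        if motif.strand != "-":
            return None
        gap = edge - motif.end
    return gap if gap >= 0 else None


def attach_rss(
    candidates: list[GeneSegment],
    rss_hits: list[RssMotif],
    max_gap: int = 10,
    config: RssConfig | None = None,
) -> list[GeneSegment]:
    """Assign each V/J draft its nearest correctly oriented RSS.

    A V draft takes the closest motif (with an allowed V spacer) starting
    within ``max_gap`` nt of its coding 3' end; a J draft the closest
    within ``max_gap`` of its coding 5' end.  Drafts with no such hit are
    flagged ``missing_rss``.  Drafts are modified in place and returned.
    """
    config = config or RssConfig()
    for seg in candidates:
        if seg.segment_type not in "VJ":
            continue
        allowed = config.v_spacers if seg.segment_type == "V" else config.j_spacers
        best: tuple[int, RssMotif] | None = None
        for motif in rss_hits:
            if motif.spacer_length not in allowed:
                continue
            gap = _edge_gap(seg, motif)
            if gap is None or gap > max_gap:
                continue
            if best is None or gap < best[0]:
                best = (gap, motif)
        if best is not None:
            seg.rss = [best[1]]
        else:
            seg.rss = []
            if "missing_rss" not in seg.defect_reasons:
                seg.defect_reasons.append("missing_rss")
    return candidates


def detect_d_segments(
    rss_hits: list[RssMotif],
    contig: str,
    max_d_length: int = 40,
    region: tuple[int, int] | None = None,
    config: RssConfig | None = None,
) -> list[GeneSegment]:
    """Report a D segment for each facing pair of RSS hits.

    A D gene is bounded by two RSSs in opposite orientation whose
    heptamers face each other across a core of 1..``max_d_length`` nt.
    Under the 12/23 rule one flank carries the short (12-bp) spacer and
    the other a long (22/23-bp) spacer; the D strand is '+' when the
    short spacer lies on its genomic 5' (left) flank.
    """
    config = config or RssConfig()
    if region is not None:
        lo, hi = region
        if lo > hi:
            raise ValueError("invalid region")
        rss_hits = [m for m in rss_hits if m.start >= lo and m.end <= hi]
    left_flanks = [m for m in rss_hits if m.strand == "-"]  # heptamer at right
    right_flanks = [m for m in rss_hits if m.strand == "+"]  # heptamer at left
    drafts: list[GeneSegment] = []
    seen: set[tuple[int, int]] = set()
    for left in left_flanks:
        for right in right_flanks:
            core = (left.end, right.start)
            if not 1 <= core[1] - core[0] <= max_d_length:
                continue
            spacers = (left.spacer_length, right.spacer_length)
            if left.spacer_length in config.d_spacers_short and (
                right.spacer_length in config.d_spacers_long
            ):
                strand = "+"
            elif left.spacer_length in config.d_spacers_long and (
                right.spacer_length in config.d_spacers_short
            ):
                strand = "-"
            else:
                log.debug("rejecting D candidate %s: spacers %s", core, spacers)
                continue
            if core in seen:
                continue
            seen.add(core)
            drafts.append(
                GeneSegment(
                    segment_type="D",
                    contig=contig,
                    coding_intervals=[core],
                    strand=strand,
                    functionality="functional",
                    rss=[left, right],
                )
            )
    drafts.sort(key=lambda d: d.start)
    return drafts
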