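"""Six-frame homology scan of a genome against reference V/C proteins.

A seed-and-extend local aligner: exact amino-acid k-mer seeds locate
candidate diagonals in the six-frame translation, and each candidate
window is then scored with a BLOSUM62 local alignment (affine gaps,
open 11 / extend 1).  Scores are raw alignment scores.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .model import GenomicSequence, ReferenceProtein, revcomp

SEED_K = 6
_WINDOW_PAD = 12


@dataclass(frozen=True)
class CodingCandidate:
    """A maximal-scoring local protein-level hit in genome coordinates."""

    interval: tuple[int, int]
    strand: str
    frame: int
    score: float
    ref: ReferenceProtein


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _six_frames(residues: str) -> list[tuple[str, int, str]]:
    """(strand, frame, protein) for all six reading frames."""
    frames = []
    for strand, seq in (("+", residues), ("-", revcomp(residues))):
        for f in range(3):
            usable = (len(seq) - f) // 3 * 3
            prot = str(Seq(seq[f : f + usable]).translate())
            frames.append((strand, f, prot))
    return frames


def _seed_index(refs: list[ReferenceProtein]) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, ref in enumerate(refs):
        for p in range(len(ref.seq) - SEED_K + 1):
            index.setdefault(ref.seq[p : p + SEED_K], []).append((ri, p))
    return index


def _windows_for_frame(
    prot: str, index: dict[str, list[tuple[int, int]]], refs: list[ReferenceProtein]
) -> dict[int, list[tuple[int, int]]]:
    """Merged candidate windows (protein coords) per reference index."""
    diag_hits: dict[tuple[int, int], list[int]] = {}
    for p in range(len(prot) - SEED_K + 1):
        for ri, rp in index.get(prot[p : p + SEED_K], ()):
            diag_hits.setdefault((ri, p - rp), []).append(p)
    windows: dict[int, list[tuple[int, int]]] = {}
    for (ri, diag), positions in diag_hits.items():
        ref_len = len(refs[ri].seq)
        lo = max(0, diag - _WINDOW_PAD)
        hi = min(len(prot), diag + ref_len + _WINDOW_PAD)
        windows.setdefault(ri, []).append((lo, hi))
    # merge overlapping windows per reference
    merged: dict[int, list[tuple[int, int]]] = {}
    for ri, wins in windows.items():
        wins.sort()
        out = [wins[0]]
        for lo, hi in wins[1:]:
            if lo <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], hi))
            else:
                out.append((lo, hi))
        merged[ri] = out
    return merged


def _protein_to_genome(
    p0: int, p1: int, strand: str, frame: int, genome_len: int
) -> tuple[int, int]:
    nt0, nt1 = frame + 3 * p0, frame + 3 * p1
    if strand == "+":
        return nt0, nt1
    return genome_len - nt1, genome_len - nt0


def find_coding_candidates(
    genome: GenomicSequence,
    reference_proteins: list[ReferenceProtein],
    min_score: float = 100.0,
) -> list[CodingCandidate]:
    """Locate reference-protein homologues in all six frames of ``genome``.

    Returns the best-scoring non-overlapping candidates (per strand) with
    raw BLOSUM62 local-alignment score >= ``min_score``, sorted by start.
    """
    if not reference_proteins:
        raise ValueError("reference protein set must not be empty")
    if len(genome) == 0:
        raise ValueError("genome must not be empty")
    refs = list(reference_proteins)
    index = _seed_index(refs)
    aligner = _make_aligner()
    n = len(genome)
    raw: list[CodingCandidate] = []
    for strand, frame, prot in _six_frames(genome.residues):
        for ri, wins in _windows_for_frame(prot, index, refs).items():
            ref = refs[ri]
            for lo, hi in wins:
                window = prot[lo:hi]
                alignments = aligner.align(window, ref.seq)
                if len(alignments) == 0:
                    continue
                best = alignments[0]
                if best.score < min_score:
                    continue
                blocks = best.aligned[0]
                p0, p1 = lo + int(blocks[0][0]), lo + int(blocks[-1][1])
                interval = _protein_to_genome(p0, p1, strand, frame, n)
                raw.append(
                    CodingCandidate(interval, strand, frame, float(best.score), ref)
                )
    return _drop_overlaps(raw)


def _drop_overlaps(candidates: list[CodingCandidate]) -> list[CodingCandidate]:
    """Keep the best-scoring candidate among mutually overlapping hits on
    the same strand."""
    kept: list[CodingCandidate] = []
    for cand in sorted(candidates, key=lambda c: -c.score):
        s0, e0 = cand.interval
        clash = any(
            c.strand == cand.strand and s0 < c.interval[1] and c.interval[0] < e0
            for c in kept
        )
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: c.interval)
    return kept
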