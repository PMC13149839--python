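"""Synthetic cod-like TR locus construction with ground truth.

Presets emulate the three locus architectures of the Atlantic cod TR
system:

* ``cod_AD`` — a single alpha/delta translocon: 52 V genes in forward
  orientation (five subgroups; subgroup 5 is delta-preferential and
  carries a 23-bp spacer RSS with the ACATAAACC nonamer variant; one
  subgroup-1 gene is planted as a missing-Cys104 pseudogene), then an
  alpha C gene, 21 J genes, and a delta C/J/D set, all in reverse
  orientation.  The germline V-J and V-D-J junctions are out of frame,
  so zero-trim zero-insertion rearrangements are non-productive.
* ``cod_B`` — three consecutive translocons with 10/10/14 V genes, one
  D, 8/7/8 J genes (the last J of each translocon distinctly longer)
  and one C gene each, all forward.
* ``cod_G`` — six complete V-J-C mini-clusters in forward orientation
  plus one partial (V-J, no C) mini-cluster in reverse.

Every gene is planted together with its RSS; intergenic spacer is
random sequence, re-drawn where it would contain a chance RSS hit, so
the planted motif set is exactly the recoverable one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .functionality import find_j_anchor, translate_frame
from .model import (
    CANONICAL_HEPTAMER,
    CANONICAL_NONAMER,
    GeneSegment,
    GenomicSequence,
    LocusMap,
    ReferenceProtein,
    RssMotif,
    revcomp,
)
from .naming import NamingConfig, assign_names
from .rss import RssConfig, scan_rss

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_C = _AA20.replace("C", "")

_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

#: nt appended after the 2nd-CYS codon (the germline CDR3 opening)
V_AFTER_CYS = 2
#: fixed tail after the J anchor G-X-G codons
J_TAIL = 6
ANCHOR_NT = 12  # F/W + G + X + G codons


# ---------------------------------------------------------------------------
# germline containers
# ---------------------------------------------------------------------------


@dataclass
class GermlineGene:
    """One germline segment as used by the recombination simulator."""

    name: str
    kind: str  # V, D, J, C
    chain: str
    seq: str
    translocon: Optional[int] = None
    cys_start: Optional[int] = None  # V: nt offset of the 2nd-CYS codon
    anchor_start: Optional[int] = None  # J: nt offset of the F/W codon
    frame: Optional[int] = None  # J reading frame

    def __post_init__(self) -> None:
        if self.kind == "V":
            if self.cys_start is None or not 0 <= self.cys_start <= len(self.seq) - 3:
                raise ValueError(f"V gene {self.name}: bad cys anchor")
            codon = self.seq[self.cys_start : self.cys_start + 3]
            if translate_frame(codon) != "C":
                raise ValueError(f"V gene {self.name}: anchor codon is not Cys")
        if self.kind == "J":
            if self.anchor_start is None or self.frame is None:
                raise ValueError(f"J gene {self.name}: missing anchor/frame")
            aa = translate_frame(self.seq[self.anchor_start : self.anchor_start + 3])
            if aa not in ("F", "W"):
                raise ValueError(f"J gene {self.name}: anchor codon is not F/W")


@dataclass
class GermlineSet:
    """Germline gene pools per chain (A, B, G, D)."""

    genes: dict[str, dict[str, list[GermlineGene]]] = field(default_factory=dict)

    def add(self, gene: GermlineGene) -> None:
        pool = self.genes.setdefault(gene.chain, {k: [] for k in "VDJC"})
        pool[gene.kind].append(gene)

    def pool(self, chain: str, kind: str) -> list[GermlineGene]:
        return self.genes.get(chain, {}).get(kind, [])

    @property
    def chains(self) -> list[str]:
        return sorted(self.genes)


def germline_to_dict(germline: GermlineSet) -> dict:
    out: dict = {}
    for chain, pools in germline.genes.items():
        out[chain] = {
            kind: [
                {
                    "name": g.name,
                    "seq": g.seq,
                    "translocon": g.translocon,
                    "cys_start": g.cys_start,
                    "anchor_start": g.anchor_start,
                    "frame": g.frame,
                }
                for g in genes
            ]
            for kind, genes in pools.items()
        }
    return out


def germline_from_dict(data: dict) -> GermlineSet:
    germline = GermlineSet()
    for chain, pools in data.items():
        for kind, genes in pools.items():
            for g in genes:
                germline.add(
                    GermlineGene(
                        name=g["name"],
                        kind=kind,
                        chain=chain,
                        seq=g["seq"],
                        translocon=g.get("translocon"),
                        cys_start=g.get("cys_start"),
                        anchor_start=g.get("anchor_start"),
                        frame=g.get("frame"),
                    )
                )
    return germline


@dataclass
class FixtureLocus:
    """A generated locus: sequence, truth annotation, germline, refs."""

    genome: GenomicSequence
    truth: LocusMap
    germline: GermlineSet
    refs: list[ReferenceProtein]


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _rand_protein(rng: np.random.Generator, n: int, alphabet: str = _AA_NO_C) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _back_translate(prot: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in prot
    )


def _mutate_protein(
    prot: str, rng: np.random.Generator, n_mut: int, protect: int = 3
) -> str:
    """Substitute ``n_mut`` distinct interior residues (termini protected)."""
    interior = np.arange(protect, len(prot) - protect)
    sites = rng.choice(interior, size=n_mut, replace=False)
    out = list(prot)
    for p in sites:
        choices = _AA_NO_C.replace(out[p], "")
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _motif(rng: np.random.Generator, spacer: int, nonamer: str = CANONICAL_NONAMER) -> str:
    return CANONICAL_HEPTAMER + _rand_nt(rng, spacer) + nonamer


def _make_v_nt(
    prot: str, rng: np.random.Generator, pseudo_missing_cys: bool = False
) -> str:
    """V coding nt: back-translated protein (terminal Cys) + CDR3 opening.

    For the missing-Cys pseudogene the terminal Cys is replaced by Gly,
    re-drawing codons until no shifted-frame Cys confounds the terminal
    window (so classification sees a clean missing-Cys case).
    """
    if pseudo_missing_cys:
        prot = prot[:-1] + "G"
        # Met/Trp near the terminus can force a shifted-frame Cys codon
        # (e.g. ATG followed by a T/C-starting codon), which would read
        # as a frameshift rather than a clean missing-Cys case
        tail_aa = prot[-6:].replace("M", "G").replace("W", "G")
        prot = prot[:-6] + tail_aa
    for _ in range(200):
        nt = _back_translate(prot, rng) + _rand_nt(rng, V_AFTER_CYS)
        if pseudo_missing_cys:
            tail = nt[-(3 * 4 + V_AFTER_CYS + 2) :]
            if any("C" in translate_frame(tail, f) for f in range(3)):
                continue
        return nt
    raise RuntimeError("could not realise V gene nucleotide sequence")


def _make_j_nt(
    rng: np.random.Generator, j_before: int
) -> tuple[str, int, int]:
    """J coding nt with the F/W-G-X-G anchor at offset ``j_before``.

    Returns (nt, anchor_start, frame).  The leading region is re-drawn
    until the planted anchor is the earliest anchor in any frame and the
    anchor-frame reading is stop-free.
    """
    frame = j_before % 3
    f_codons = ["TTT", "TTC", "TGG"]
    g_codons = ["GGT", "GGC", "GGA", "GGG"]
    for _ in range(500):
        pre = _rand_nt(rng, j_before)
        x = _CODONS[_AA20[rng.integers(0, 20)]]
        anchor = (
            f_codons[rng.integers(0, 3)]
            + g_codons[rng.integers(0, 4)]
            + x[rng.integers(0, len(x))]
            + g_codons[rng.integers(0, 4)]
        )
        nt = pre + anchor + _rand_nt(rng, J_TAIL)
        found = [a for a in (find_j_anchor(nt, f) for f in range(3)) if a is not None]
        if min(found) != j_before:
            continue
        if "*" in translate_frame(nt, frame):
            continue  # whole anchor-frame reading must be stop-free
        return nt, j_before, frame
    raise RuntimeError("could not realise J gene nucleotide sequence")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass
class _Feature:
    """A planted gene in cassette-local (forward-form) coordinates."""

    kind: str
    chain: str
    interval: tuple[int, int]
    rss_intervals: list[tuple[int, int, int, str, str]]  # (s, e, spacer, strand, nonamer)
    subgroup: Optional[int] = None
    group_id: Optional[int] = None
    frame: int = 0
    functionality: str = "functional"
    defects: list[str] = field(default_factory=list)
    germline: Optional[GermlineGene] = None


class _Assembler:
    def __init__(self, contig: str, rng: np.random.Generator) -> None:
        self.contig = contig
        self.rng = rng
        self.blocks: list[list] = []  # [kind, seq] with kind fixed|inter
        self.features: list[tuple[int, _Feature, str]] = []  # (block_idx, feat, strand)

    @property
    def length(self) -> int:
        return sum(len(b[1]) for b in self.blocks)

    def intergenic(self, lo: int = 200, hi: int = 400) -> None:
        n = int(self.rng.integers(lo, hi + 1))
        self.blocks.append(["inter", _rand_nt(self.rng, n)])

    def cassette(self, seq: str, feats: list[_Feature], strand: str) -> None:
        """Insert a forward-form cassette, reverse-complementing it (and
        mirroring feature coordinates) when ``strand`` is '-'."""
        if strand == "-":
            seq = revcomp(seq)
        self.blocks.append(["fixed", seq])
        for feat in feats:
            self.features.append((len(self.blocks) - 1, feat, strand))

    def _block_offsets(self) -> list[int]:
        offs, pos = [], 0
        for _, seq in self.blocks:
            offs.append(pos)
            pos += len(seq)
        return offs

    def finish(self, rss_config: RssConfig) -> tuple[GenomicSequence, list[GeneSegment]]:
        self._scrub_intergenic(rss_config)
        offs = self._block_offsets()
        genome = GenomicSequence(self.contig, "".join(b[1] for b in self.blocks))
        segments = []
        for bi, feat, strand in self.features:
            base, blen = offs[bi], len(self.blocks[bi][1])

            def to_genome(iv: tuple[int, int]) -> tuple[int, int]:
                if strand == "+":
                    return base + iv[0], base + iv[1]
                return base + blen - iv[1], base + blen - iv[0]

            s, e = to_genome(feat.interval)
            motifs = []
            for rs, re_, spacer, mstrand, nonamer in feat.rss_intervals:
                gs, ge = to_genome((rs, re_))
                gstrand = mstrand if strand == "+" else ("-" if mstrand == "+" else "+")
                hept = (
                    genome.residues[gs : gs + 7]
                    if gstrand == "+"
                    else revcomp(genome.residues[ge - 7 : ge])
                )
                non = (
                    genome.residues[ge - 9 : ge]
                    if gstrand == "+"
                    else revcomp(genome.residues[gs : gs + 9])
                )
                motifs.append(
                    RssMotif(
                        heptamer_seq=hept,
                        nonamer_seq=non,
                        spacer_length=spacer,
                        heptamer_mismatches=sum(
                            a != b for a, b in zip(hept, CANONICAL_HEPTAMER)
                        ),
                        nonamer_mismatches=sum(
                            a != b for a, b in zip(non, CANONICAL_NONAMER)
                        ),
                        start=gs,
                        end=ge,
                        strand=gstrand,
                    )
                )
            motifs.sort(key=lambda m: m.start)
            seg_strand = strand if feat.kind != "D" else feat._d_strand  # type: ignore[attr-defined]
            seg = GeneSegment(
                segment_type=feat.kind,
                contig=self.contig,
                coding_intervals=[(s, e)],
                strand=seg_strand,
                frame=feat.frame,
                chain=feat.chain,
                functionality=feat.functionality,
                defect_reasons=list(feat.defects),
                subgroup=feat.subgroup,
                group_id=feat.group_id,
                rss=motifs,
            )
            seg._germline = feat.germline  # type: ignore[attr-defined]
            segments.append(seg)
        segments.sort(key=lambda x: x.start)
        return genome, segments

    def _scrub_intergenic(self, rss_config: RssConfig, max_rounds: int = 6) -> None:
        """Re-draw intergenic blocks that happen to contain RSS-like hits,
        so chance motifs cannot shadow the planted annotation."""
        for _ in range(max_rounds):
            offs = self._block_offsets()
            genome = GenomicSequence(self.contig, "".join(b[1] for b in self.blocks))
            hits = scan_rss(genome, rss_config)
            planted: set[tuple[int, int]] = set()
            for bi, feat, strand in self.features:
                base, blen = offs[bi], len(self.blocks[bi][1])
                for rs, re_, *_ in feat.rss_intervals:
                    if strand == "+":
                        planted.add((base + rs, base + re_))
                    else:
                        planted.add((base + blen - re_, base + blen - rs))
            dirty = set()
            for hit in hits:
                if (hit.start, hit.end) in planted:
                    continue
                for bi, (kind, seq) in enumerate(self.blocks):
                    if kind != "inter":
                        continue
                    lo, hi = offs[bi], offs[bi] + len(seq)
                    if hit.start < hi and lo < hit.end:
                        dirty.add(bi)
            if not dirty:
                return
            for bi in dirty:
                self.blocks[bi][1] = _rand_nt(self.rng, len(self.blocks[bi][1]))


# ---------------------------------------------------------------------------
# cassette builders (forward form)
# ---------------------------------------------------------------------------


def _v_cassette(
    nt: str,
    rng: np.random.Generator,
    spacer: int,
    nonamer: str,
    chain: str,
    subgroup: int,
    group_id: int,
    germ: Optional[GermlineGene],
    functionality: str = "functional",
    defects: tuple[str, ...] = (),
) -> tuple[str, list[_Feature]]:
    motif = _motif(rng, spacer, nonamer)
    seq = nt + motif
    feat = _Feature(
        kind="V",
        chain=chain,
        interval=(0, len(nt)),
        rss_intervals=[(len(nt), len(seq), spacer, "+", nonamer)],
        subgroup=subgroup,
        group_id=group_id,
        functionality=functionality,
        defects=list(defects),
        germline=germ,
    )
    return seq, [feat]


def _j_cassette(
    nt: str,
    anchor: int,
    frame: int,
    rng: np.random.Generator,
    chain: str,
    group_id: int,
    germ: Optional[GermlineGene],
) -> tuple[str, list[_Feature]]:
    motif = revcomp(_motif(rng, 12))
    seq = motif + nt
    feat = _Feature(
        kind="J",
        chain=chain,
        interval=(len(motif), len(seq)),
        rss_intervals=[(0, len(motif), 12, "-", CANONICAL_NONAMER)],
        frame=frame,
        group_id=group_id,
        germline=germ,
    )
    return seq, [feat]


def _d_cassette(
    core: str,
    rng: np.random.Generator,
    chain: str,
    group_id: int,
    germ: Optional[GermlineGene],
) -> tuple[str, list[_Feature]]:
    left = revcomp(_motif(rng, 12))
    right = _motif(rng, 23)
    seq = left + core + right
    feat = _Feature(
        kind="D",
        chain=chain,
        interval=(len(left), len(left) + len(core)),
        rss_intervals=[
            (0, len(left), 12, "-", CANONICAL_NONAMER),
            (len(left) + len(core), len(seq), 23, "+", CANONICAL_NONAMER),
        ],
        group_id=group_id,
        germline=germ,
    )
    feat._d_strand = "+"  # type: ignore[attr-defined]
    return seq, [feat]


def _c_cassette(
    nt: str, chain: str, group_id: int, germ: Optional[GermlineGene]
) -> tuple[str, list[_Feature]]:
    feat = _Feature(
        kind="C",
        chain=chain,
        interval=(0, len(nt)),
        rss_intervals=[],
        group_id=group_id,
        germline=germ,
    )
    return nt, [feat]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _fix_d_strand(segments: list[GeneSegment]) -> None:
    """D strand follows the 12/23 rule: '+' when the 12-spacer flank is
    on the genomic left."""
    for seg in segments:
        if seg.segment_type == "D" and len(seg.rss) == 2:
            left = min(seg.rss, key=lambda m: m.start)
            seg.strand = "+" if left.spacer_length == 12 else "-"


def _collect_germline(segments: list[GeneSegment], germline: GermlineSet) -> None:
    for seg in segments:
        germ = getattr(seg, "_germline", None)
        if germ is not None:
            germ.name = seg.name
            germline.add(germ)


def _build_cod_ad(rng: np.random.Generator) -> FixtureLocus:
    v_len = 98
    subgroup_sizes = {1: 14, 2: 11, 3: 8, 4: 10, 5: 9}
    founders = {sg: _rand_protein(rng, v_len - 1) + "C" for sg in subgroup_sizes}
    n_mut = round(0.07 * v_len)

    # placement order pins subgroup labels: one gene of subgroups 1-4
    # first, the rest of 1-4 shuffled, the delta subgroup (5) last
    order = [1, 2, 3, 4]
    rest = [sg for sg in (1, 2, 3, 4) for _ in range(subgroup_sizes[sg] - 1)]
    rng.shuffle(rest)
    order += rest + [5] * subgroup_sizes[5]

    asm = _Assembler("chr8_AD", rng)
    asm.intergenic()
    sg1_seen = 0
    for sg in order:
        prot = _mutate_protein(founders[sg], rng, n_mut)
        chain = "D" if sg == 5 else "A"
        pseudo = False
        if sg == 1:
            sg1_seen += 1
            pseudo = sg1_seen == 9  # planted missing-Cys104 pseudogene
        nt = _make_v_nt(prot, rng, pseudo_missing_cys=pseudo)
        germ = None
        if not pseudo:
            germ = GermlineGene(
                name="", kind="V", chain=chain, seq=nt, cys_start=len(nt) - 3 - V_AFTER_CYS
            )
        spacer = 23 if sg == 5 else 22
        nonamer = "ACATAAACC" if sg == 5 else CANONICAL_NONAMER
        seq, feats = _v_cassette(
            nt,
            rng,
            spacer,
            nonamer,
            chain,
            sg,
            1,
            germ,
            functionality="pseudogene" if pseudo else "functional",
            defects=("missing_cys104", "incomplete_cdr3") if pseudo else (),
        )
        asm.cassette(seq, feats, "+")
        asm.intergenic()

    # reverse block: alpha C, 21 alpha J, then delta C, J, D
    c_alpha = _rand_protein(rng, 140)
    germ_ca = GermlineGene(name="", kind="C", chain="A", seq="")
    nt_ca = _back_translate(c_alpha, rng)
    germ_ca.seq = nt_ca
    seq, feats = _c_cassette(nt_ca, "A", 1, germ_ca)
    asm.cassette(seq, feats, "-")
    asm.intergenic()
    for _ in range(21):
        j_before = int(rng.choice([24, 27, 30]))  # keeps germline VJ out of frame
        nt, anchor, frame = _make_j_nt(rng, j_before)
        germ = GermlineGene(
            name="", kind="J", chain="A", seq=nt, anchor_start=anchor, frame=frame
        )
        seq, feats = _j_cassette(nt, anchor, frame, rng, "A", 1, germ)
        asm.cassette(seq, feats, "-")
        asm.intergenic()
    c_delta = _rand_protein(rng, 140)
    nt_cd = _back_translate(c_delta, rng)
    germ_cd = GermlineGene(name="", kind="C", chain="D", seq=nt_cd)
    seq, feats = _c_cassette(nt_cd, "D", 1, germ_cd)
    asm.cassette(seq, feats, "-")
    asm.intergenic()
    nt, anchor, frame = _make_j_nt(rng, 27)
    germ = GermlineGene(name="", kind="J", chain="D", seq=nt, anchor_start=anchor, frame=frame)
    seq, feats = _j_cassette(nt, anchor, frame, rng, "D", 1, germ)
    asm.cassette(seq, feats, "-")
    asm.intergenic()
    d_core = _rand_nt(rng, 12)
    germ_d = GermlineGene(name="", kind="D", chain="D", seq=d_core)
    seq, feats = _d_cassette(d_core, rng, "D", 1, germ_d)
    asm.cassette(seq, feats, "-")
    asm.intergenic()

    genome, segments = asm.finish(RssConfig())
    _fix_d_strand(segments)
    truth = LocusMap(contig=genome.id, segments=segments)
    truth.translocons = [(1, (segments[0].start, segments[-1].end))]
    assign_names(truth, "A/D", NamingConfig(delta_subgroups={5: 1}))
    germline = GermlineSet()
    _collect_germline(truth.segments, germline)

    refs = [
        ReferenceProtein(f"ref_V_sg{sg}", founders[sg], "D" if sg == 5 else "A", "V")
        for sg in subgroup_sizes
    ]
    refs.append(ReferenceProtein("ref_C_alpha", c_alpha, "A", "C"))
    refs.append(ReferenceProtein("ref_C_delta", c_delta, "D", "C"))
    # germline D genes recombine at both ends; the delta D has no anchor
    return FixtureLocus(genome, truth, germline, refs)


def _build_cod_b(rng: np.random.Generator) -> FixtureLocus:
    v_len = 96
    founders = {sg: _rand_protein(rng, v_len - 1) + "C" for sg in range(1, 10)}
    n_mut = round(0.07 * v_len)
    layouts = {
        1: [1, 2, 3, 4, 5, 6, 7, 1, 1, 2],
        2: [1, 2, 3, 4, 5, 6, 7, 1, 1, 2],
        3: [1, 2, 3, 4, 5, 6, 7, 8, 9, 1, 1, 2, 5, 1],
    }
    j_counts = {1: 8, 2: 7, 3: 8}
    c_founder = _rand_protein(rng, 175)
    asm = _Assembler("chr5_B", rng)
    asm.intergenic()
    for t in (1, 2, 3):
        for sg in layouts[t]:
            prot = _mutate_protein(founders[sg], rng, n_mut)
            nt = _make_v_nt(prot, rng)
            germ = GermlineGene(
                name="",
                kind="V",
                chain="B",
                seq=nt,
                translocon=t,
                cys_start=len(nt) - 3 - V_AFTER_CYS,
            )
            spacer = 22 if sg % 2 else 23
            seq, feats = _v_cassette(
                nt, rng, spacer, CANONICAL_NONAMER, "B", sg, t, germ
            )
            asm.cassette(seq, feats, "+")
            asm.intergenic()
        d_core = _rand_nt(rng, 14)
        germ_d = GermlineGene(name="", kind="D", chain="B", seq=d_core, translocon=t)
        seq, feats = _d_cassette(d_core, rng, "B", t, germ_d)
        asm.cassette(seq, feats, "+")
        asm.intergenic()
        for jn in range(j_counts[t]):
            terminal = jn == j_counts[t] - 1
            j_before = 52 if terminal else 26  # terminal J distinctly longer
            nt, anchor, frame = _make_j_nt(rng, j_before)
            germ = GermlineGene(
                name="",
                kind="J",
                chain="B",
                seq=nt,
                translocon=t,
                anchor_start=anchor,
                frame=frame,
            )
            seq, feats = _j_cassette(nt, anchor, frame, rng, "B", t, germ)
            asm.cassette(seq, feats, "+")
            asm.intergenic()
        c_prot = _mutate_protein(c_founder, rng, round(0.10 * len(c_founder)))
        nt_c = _back_translate(c_prot, rng)
        germ_c = GermlineGene(name="", kind="C", chain="B", seq=nt_c, translocon=t)
        seq, feats = _c_cassette(nt_c, "B", t, germ_c)
        asm.cassette(seq, feats, "+")
        asm.intergenic()

    genome, segments = asm.finish(RssConfig())
    _fix_d_strand(segments)
    truth = LocusMap(contig=genome.id, segments=segments)
    spans: dict[int, list[int]] = {}
    for s in segments:
        spans.setdefault(s.group_id, []).extend([s.start, s.end])
    truth.translocons = [(t, (min(v), max(v))) for t, v in sorted(spans.items())]
    assign_names(truth, "B")
    germline = GermlineSet()
    _collect_germline(truth.segments, germline)
    refs = [
        ReferenceProtein(f"ref_V_sg{sg}", founders[sg], "B", "V") for sg in founders
    ]
    refs.append(ReferenceProtein("ref_C_beta", c_founder, "B", "C"))
    return FixtureLocus(genome, truth, germline, refs)


def _build_cod_g(rng: np.random.Generator) -> FixtureLocus:
    v_len = 94
    founder = _rand_protein(rng, v_len - 1) + "C"
    n_mut = round(0.06 * v_len)
    c_founder = _rand_protein(rng, 130)
    asm = _Assembler("chr8_G", rng)
    asm.intergenic()
    clusters = []
    for k in range(1, 8):
        partial = k == 7
        strand = "-" if partial else "+"
        prot = _mutate_protein(founder, rng, n_mut)
        nt_v = _make_v_nt(prot, rng)
        germ_v = None if partial else GermlineGene(
            name="", kind="V", chain="G", seq=nt_v, cys_start=len(nt_v) - 3 - V_AFTER_CYS
        )
        vseq, vfeats = _v_cassette(nt_v, rng, 22, CANONICAL_NONAMER, "G", 1, k, germ_v)
        nt_j, anchor, frame = _make_j_nt(rng, 28)
        germ_j = None if partial else GermlineGene(
            name="", kind="J", chain="G", seq=nt_j, anchor_start=anchor, frame=frame
        )
        jseq, jfeats = _j_cassette(nt_j, anchor, frame, rng, "G", k, germ_j)
        unit = vseq + _rand_nt(rng, 150) + jseq
        feats = vfeats + [
            _Feature(
                kind=f.kind,
                chain=f.chain,
                interval=(f.interval[0] + len(vseq) + 150, f.interval[1] + len(vseq) + 150),
                rss_intervals=[
                    (s + len(vseq) + 150, e + len(vseq) + 150, sp, st, no)
                    for s, e, sp, st, no in f.rss_intervals
                ],
                frame=f.frame,
                group_id=f.group_id,
                germline=f.germline,
            )
            for f in jfeats
        ]
        if not partial:
            c_prot = _mutate_protein(c_founder, rng, round(0.08 * len(c_founder)))
            nt_c = _back_translate(c_prot, rng)
            germ_c = GermlineGene(name="", kind="C", chain="G", seq=nt_c)
            off = len(unit) + 150
            unit = unit + _rand_nt(rng, 150) + nt_c
            feats.append(
                _Feature(
                    kind="C",
                    chain="G",
                    interval=(off, off + len(nt_c)),
                    rss_intervals=[],
                    group_id=k,
                    germline=germ_c,
                )
            )
        asm.cassette(unit, feats, strand)
        asm.intergenic(600, 900)
        clusters.append((k, not partial))

    genome, segments = asm.finish(RssConfig())
    truth = LocusMap(contig=genome.id, segments=segments)
    truth.miniclusters = [(k, [], complete) for k, complete in clusters]
    assign_names(truth, "G")
    germline = GermlineSet()
    _collect_germline(truth.segments, germline)
    refs = [
        ReferenceProtein("ref_V_gamma", founder, "G", "V"),
        ReferenceProtein("ref_C_gamma", c_founder, "G", "C"),
    ]
    return FixtureLocus(genome, truth, germline, refs)


PRESETS = {
    "cod_AD": _build_cod_ad,
    "cod_B": _build_cod_b,
    "cod_G": _build_cod_g,
}


def build_fixture_locus(preset: str, seed: int = 0) -> FixtureLocus:
    """Generate a cod-like fixture locus with exact ground truth.

    Deterministic per ``seed``: identical seeds yield byte-identical
    genomes and truth maps.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    rng = np.random.default_rng(seed)
    return PRESETS[preset](rng)
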