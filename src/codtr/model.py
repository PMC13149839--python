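"""Core domain types for TR locus annotation and repertoire analysis.

Coordinates are 0-based half-open on the forward strand of a contig
throughout the library; GFF3 output converts to 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = set("ACGTN")

CANONICAL_HEPTAMER = "CACAGTG"
CANONICAL_NONAMER = "ACAAAAACC"

#: which genomic side of the motif the recombining coding end abuts
ORIENT_CODING_5P = "coding-5'"
ORIENT_CODING_3P = "coding-3'"

DEFECT_REASONS = (
    "stop_codon",
    "frameshift",
    "missing_rss",
    "missing_cys104",
    "incomplete_cdr3",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC subset A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomicSequence:
    """A contig: identifier plus residues over {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues) if c not in DNA_ALPHABET
            )
            raise ValueError(
                f"non-DNA character {self.residues[pos]!r} at position {pos} "
                f"in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "GenomicSequence":
        return GenomicSequence(self.id, revcomp(self.residues))


@dataclass(frozen=True)
class RssMotif:
    """A recombination signal sequence hit: heptamer + spacer + nonamer.

    ``start``/``end`` span heptamer through nonamer in forward-strand
    contig coordinates.  ``strand`` is '+' when the canonical motif reads
    5'->3' on the forward strand (heptamer at ``start``), '-' when it reads
    on the reverse strand (heptamer at ``end``).  The recombining coding
    end always abuts the heptamer, so orientation follows from strand.
    """

    heptamer_seq: str
    nonamer_seq: str
    spacer_length: int
    heptamer_mismatches: int
    nonamer_mismatches: int
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end - self.start != 7 + self.spacer_length + 9:
            raise ValueError(
                "RSS span does not equal heptamer + spacer + nonamer"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def orientation(self) -> str:
        """Side of the motif on which the recombining coding end lies."""
        return ORIENT_CODING_5P if self.strand == "+" else ORIENT_CODING_3P

    @property
    def heptamer_edge(self) -> int:
        """Contig coordinate of the heptamer edge abutting the coding end."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneSegment:
    """An annotated V/D/J/C gene segment on a contig."""

    segment_type: str  # V, D, J, C
    contig: str
    coding_intervals: list[tuple[int, int]]
    strand: str
    frame: int = 0
    chain: Optional[str] = None  # A, B, G, D or A/D
    name: Optional[str] = None
    functionality: Optional[str] = None  # functional | pseudogene
    defect_reasons: list[str] = field(default_factory=list)
    subgroup: Optional[int] = None
    group_id: Optional[int] = None  # translocon or mini-cluster index
    rss: list[RssMotif] = field(default_factory=list)
    score: Optional[float] = None
    ref_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.segment_type not in "VDJC":
            raise ValueError(f"bad segment type {self.segment_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.coding_intervals = sorted(tuple(iv) for iv in self.coding_intervals)

    @property
    def start(self) -> int:
        return self.coding_intervals[0][0]

    @property
    def end(self) -> int:
        return self.coding_intervals[-1][1]

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals)

    def coding_sequence(self, genome: GenomicSequence) -> str:
        """Spliced coding sequence read 5'->3' on the segment's own strand."""
        parts = [genome.residues[s:e] for s, e in self.coding_intervals]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    @property
    def recombining_edge(self) -> int:
        """Contig coordinate of the coding end that recombines.

        V genes recombine at their coding 3' end, J genes at their coding
        5' end.  D genes recombine at both and are handled separately.
        """
        if self.segment_type == "V":
            return self.end if self.strand == "+" else self.start
        if self.segment_type == "J":
            return self.start if self.strand == "+" else self.end
        raise ValueError(f"no single recombining edge for {self.segment_type}")

    def validate(self) -> None:
        if self.functionality == "pseudogene" and not self.defect_reasons:
            raise ValueError(f"pseudogene {self.name} without defect reasons")
        if self.functionality == "functional":
            if self.segment_type in "VJ" and len(self.rss) != 1:
                raise ValueError(
                    f"functional {self.segment_type} {self.name} must carry "
                    f"exactly one RSS (has {len(self.rss)})"
                )
        if self.segment_type == "D" and len(self.rss) == 2:
            if self.rss[0].strand == self.rss[1].strand:
                raise ValueError("D RSS pair must be in opposite orientation")


@dataclass
class LocusMap:
    """Ordered gene segments of one contig with their groupings."""

    contig: str
    segments: list[GeneSegment]
    translocons: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    miniclusters: list[tuple[int, list[str], bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.start, s.end))
        starts = [s.start for s in self.segments]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("segments not sortable by start")

    def by_type(self, segment_type: str) -> list[GeneSegment]:
        return [s for s in self.segments if s.segment_type == segment_type]

    def by_name(self, name: str) -> GeneSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def translocon_of(self) -> dict[str, int]:
        """Map segment name -> translocon/cluster index (named segments)."""
        return {
            s.name: s.group_id
            for s in self.segments
            if s.name is not None and s.group_id is not None
        }


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference V or C protein used to seed the homology scan."""

    id: str
    seq: str
    chain: str  # A, B, G, D
    ptype: str  # V or C

    def __post_init__(self) -> None:
        if self.ptype not in ("V", "C"):
            raise ValueError(f"reference type must be V or C, got {self.ptype}")
        if not re.fullmatch(r"[A-Z*]+", self.seq):
            raise ValueError(f"bad protein residues in reference {self.id}")


# ---------------------------------------------------------------------------
# expressed-repertoire types
# ---------------------------------------------------------------------------


@dataclass
class Clonotype:
    """A CDR3-collapsed receptor record.

    ``v_call``/``j_call`` are sets of germline names; more than one name
    means the assignment was ambiguous.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_call: frozenset[str]
    j_call: frozenset[str]
    duplicate_count: int
    productive: bool

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")
        self.v_call = frozenset(self.v_call)
        self.j_call = frozenset(self.j_call)

    @property
    def ambiguous_v(self) -> bool:
        return len(self.v_call) > 1

    @property
    def ambiguous_j(self) -> bool:
        return len(self.j_call) > 1


@dataclass
class RepertoireSample:
    """One sequenced (or simulated) repertoire of a single chain."""

    sample_id: str
    clonotypes: list[Clonotype]
    fish_id: Optional[str] = None
    chain: Optional[str] = None
    replicate: Optional[str] = None
    total_mapped_reads: Optional[int] = None
    sampling_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.total_mapped_reads is not None:
            if self.total_reads > self.total_mapped_reads:
                raise ValueError("clonotype reads exceed total_mapped_reads")

    @property
    def total_reads(self) -> int:
        return sum(c.duplicate_count for c in self.clonotypes)

    @property
    def unique_nt(self) -> int:
        return len({c.cdr3_nt for c in self.clonotypes})

    @property
    def unique_aa(self) -> int:
        return len({c.cdr3_aa for c in self.clonotypes})


@dataclass
class SimulatedClonotype:
    """A simulated rearrangement with its hidden recombination truth."""

    v_id: str
    j_id: str
    junction_nt: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    d_id: Optional[str] = None
    trims: dict[str, int] = field(default_factory=dict)
    insertions: dict[str, str] = field(default_factory=dict)
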