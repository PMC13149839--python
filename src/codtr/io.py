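"""Readers and writers: FASTA, GFF3, AIRR-style TSV, config, manifest.

All writers and readers are inverse on valid data.  GFF3 output uses
1-based inclusive coordinates (the library is 0-based half-open
internally); segment features carry RSS motifs as child features.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Clonotype,
    GeneSegment,
    GenomicSequence,
    LocusMap,
    ReferenceProtein,
    RepertoireSample,
    RssMotif,
)

log = logging.getLogger(__name__)

__version__ = "0.1.0"

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_IUPAC_AA = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Read FASTA records as (id, residues); uppercases and validates.

    Lowercase input is uppercased (logged); duplicate ids and
    non-IUPAC characters are errors.
    """
    allowed = _IUPAC_DNA if alphabet == "dna" else _IUPAC_AA
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        seq = raw.upper()
        if seq != raw:
            log.warning("sequence %s contained lowercase residues; uppercased", rec.id)
        bad = set(seq) - allowed
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"non-IUPAC character {seq[pos]!r} at position {pos} in {rec.id!r}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_genome(path: str | Path) -> list[GenomicSequence]:
    return [GenomicSequence(name, seq) for name, seq in read_fasta(path, "dna")]


def read_reference_proteins(path: str | Path) -> list[ReferenceProtein]:
    """Reference FASTA with header tokens ``chain=<A|B|G|D>`` ``type=<V|C>``."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            tok.split("=", 1) for tok in rec.description.split() if "=" in tok
        )
        if "chain" not in tokens or "type" not in tokens:
            raise ValueError(
                f"reference {rec.id!r} lacks chain=/type= header tokens"
            )
        refs.append(
            ReferenceProtein(rec.id, str(rec.seq).upper(), tokens["chain"], tokens["type"])
        )
    return refs


def write_reference_proteins(refs: list[ReferenceProtein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.id} chain={ref.chain} type={ref.ptype}\n{ref.seq}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_SEG_SO = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
    "C": "C_gene_segment",
}
_SO_SEG = {v: k for k, v in _SEG_SO.items()}


def _attr_str(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v not in (None, "", []))


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_gff3(locus: LocusMap, path: str | Path, contig_length: int | None = None) -> None:
    lines = ["##gff-version 3"]
    if contig_length is not None:
        for seg in locus.segments:
            if seg.end > contig_length:
                raise ValueError(
                    f"segment {seg.name} end {seg.end} outside contig "
                    f"of length {contig_length}"
                )
        lines.append(f"##sequence-region {locus.contig} 1 {contig_length}")
    for t, (s, e) in locus.translocons:
        lines.append(
            "\t".join(
                [
                    locus.contig, "codtr", "translocon", str(s + 1), str(e), ".",
                    "+", ".", _attr_str({"ID": f"translocon_{t}", "index": t}),
                ]
            )
        )
    for k, members, complete in locus.miniclusters:
        lines.append(
            "\t".join(
                [
                    locus.contig, "codtr", "mini_cluster", "1", "1", ".", "+", ".",
                    _attr_str(
                        {
                            "ID": f"minicluster_{k}",
                            "index": k,
                            "members": ",".join(members),
                            "complete": str(complete).lower(),
                        }
                    ),
                ]
            )
        )
    for i, seg in enumerate(locus.segments):
        seg_id = f"seg{i}"
        attrs = {
            "ID": seg_id,
            "Name": seg.name,
            "segment_type": seg.segment_type,
            "chain": seg.chain,
            "frame": seg.frame,
            "functionality": seg.functionality,
            "defect_reasons": ",".join(seg.defect_reasons),
            "subgroup": seg.subgroup,
            "group_id": seg.group_id,
        }
        if len(seg.coding_intervals) > 1:
            attrs["coding_intervals"] = ",".join(
                f"{s}-{e}" for s, e in seg.coding_intervals
            )
        lines.append(
            "\t".join(
                [
                    locus.contig, "codtr", _SEG_SO[seg.segment_type],
                    str(seg.start + 1), str(seg.end), ".", seg.strand,
                    ".", _attr_str(attrs),
                ]
            )
        )
        for r, motif in enumerate(seg.rss):
            rattrs = {
                "ID": f"{seg_id}_rss{r}",
                "Parent": seg_id,
                "spacer_length": motif.spacer_length,
                "heptamer_mismatches": motif.heptamer_mismatches,
                "nonamer_mismatches": motif.nonamer_mismatches,
                "heptamer_seq": motif.heptamer_seq,
                "nonamer_seq": motif.nonamer_seq,
            }
            lines.append(
                "\t".join(
                    [
                        locus.contig, "codtr", "recombination_signal_sequence",
                        str(motif.start + 1), str(motif.end), ".", motif.strand,
                        ".", _attr_str(rattrs),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> LocusMap:
    contig = None
    contig_length = None
    segments: dict[str, GeneSegment] = {}
    order: list[str] = []
    translocons: list[tuple[int, tuple[int, int]]] = []
    miniclusters: list[tuple[int, list[str], bool]] = []
    pending_rss: list[tuple[str, RssMotif]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            _, contig, _, length = line.split()
            contig_length = int(length)
            continue
        if not line or line.startswith("#"):
            continue
        seqid, _, ftype, start, end, _, strand, _, attr_text = line.split("\t")
        contig = contig or seqid
        attrs = _parse_attrs(attr_text)
        s0, e0 = int(start) - 1, int(end)
        if contig_length is not None and e0 > contig_length:
            raise ValueError(f"feature end {e0} outside contig of length {contig_length}")
        if ftype == "translocon":
            translocons.append((int(attrs["index"]), (s0, e0)))
        elif ftype == "mini_cluster":
            members = attrs.get("members", "")
            miniclusters.append(
                (
                    int(attrs["index"]),
                    members.split(",") if members else [],
                    attrs.get("complete") == "true",
                )
            )
        elif ftype in _SO_SEG:
            intervals = [(s0, e0)]
            if "coding_intervals" in attrs:
                intervals = [
                    tuple(int(x) for x in pair.split("-"))
                    for pair in attrs["coding_intervals"].split(",")
                ]
            seg = GeneSegment(
                segment_type=_SO_SEG[ftype],
                contig=seqid,
                coding_intervals=intervals,
                strand=strand,
                frame=int(attrs.get("frame", 0)),
                chain=attrs.get("chain"),
                name=attrs.get("Name"),
                functionality=attrs.get("functionality"),
                defect_reasons=(
                    attrs["defect_reasons"].split(",")
                    if attrs.get("defect_reasons")
                    else []
                ),
                subgroup=int(attrs["subgroup"]) if attrs.get("subgroup") else None,
                group_id=int(attrs["group_id"]) if attrs.get("group_id") else None,
            )
            segments[attrs["ID"]] = seg
            order.append(attrs["ID"])
        elif ftype == "recombination_signal_sequence":
            span = e0 - s0
            spacer = int(attrs["spacer_length"])
            motif = RssMotif(
                heptamer_seq=attrs["heptamer_seq"],
                nonamer_seq=attrs["nonamer_seq"],
                spacer_length=spacer,
                heptamer_mismatches=int(attrs["heptamer_mismatches"]),
                nonamer_mismatches=int(attrs["nonamer_mismatches"]),
                start=s0,
                end=s0 + span,
                strand=strand,
            )
            pending_rss.append((attrs["Parent"], motif))
    for parent, motif in pending_rss:
        segments[parent].rss.append(motif)
    for seg in segments.values():
        seg.rss.sort(key=lambda m: m.start)
    locus = LocusMap(
        contig=contig,
        segments=[segments[i] for i in order],
        translocons=sorted(translocons),
        miniclusters=sorted(miniclusters),
    )
    return locus


# ---------------------------------------------------------------------------
# AIRR-style clonotype tables
# ---------------------------------------------------------------------------

AIRR_COLUMNS = [
    "repertoire_id",
    "junction",
    "junction_aa",
    "v_call",
    "j_call",
    "duplicate_count",
    "productive",
]
_REQUIRED = [c for c in AIRR_COLUMNS if c != "repertoire_id"]


def write_airr(sample: RepertoireSample, path: str | Path) -> None:
    rows = [
        {
            "repertoire_id": sample.sample_id,
            "junction": c.cdr3_nt,
            "junction_aa": c.cdr3_aa,
            "v_call": ",".join(sorted(c.v_call)),
            "j_call": ",".join(sorted(c.j_call)),
            "duplicate_count": c.duplicate_count,
            "productive": "T" if c.productive else "F",
        }
        for c in sample.clonotypes
    ]
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_airr(
    path: str | Path,
    fish_id: str | None = None,
    chain: str | None = None,
    replicate: str | None = None,
    sampling_fraction: float = 0.15,
) -> RepertoireSample:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    clonotypes = []
    for i, row in df.iterrows():
        try:
            count = int(row["duplicate_count"])
        except ValueError as exc:
            raise ValueError(
                f"non-integer duplicate_count at row {i + 2} of {path}"
            ) from exc
        if count < 1:
            raise ValueError(f"duplicate_count < 1 at row {i + 2} of {path}")
        clonotypes.append(
            Clonotype(
                cdr3_nt=row["junction"],
                cdr3_aa=row["junction_aa"],
                v_call=frozenset(row["v_call"].split(",")) if row["v_call"] else frozenset(),
                j_call=frozenset(row["j_call"].split(",")) if row["j_call"] else frozenset(),
                duplicate_count=count,
                productive=str(row["productive"]).upper() in ("T", "TRUE", "1"),
            )
        )
    sample_id = (
        df["repertoire_id"].iloc[0]
        if "repertoire_id" in df.columns and len(df)
        else Path(path).stem
    )
    return RepertoireSample(
        sample_id=sample_id,
        clonotypes=clonotypes,
        fish_id=fish_id,
        chain=chain,
        replicate=replicate,
        sampling_fraction=sampling_fraction,
    )


#: column mapping from a MiXCR-style export to the AIRR fields above
MIXCR_DIALECT = {
    "cloneCount": "duplicate_count",
    "nSeqCDR3": "junction",
    "aaSeqCDR3": "junction_aa",
    "allVHitsWithScore": "v_call",
    "allJHitsWithScore": "j_call",
}


def read_mixcr(path: str | Path, **kwargs) -> RepertoireSample:
    """Read a MiXCR-style clonotype export via :data:`MIXCR_DIALECT`.

    Gene hits like ``TRB1V5-2*00(123.4)`` are stripped of allele and
    score; productivity is inferred from the aa CDR3 (no stop or
    frameshift marker).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MIXCR_DIALECT if c not in df.columns]
    if missing:
        raise ValueError(f"missing MiXCR column(s) {missing} in {path}")

    def clean_calls(text: str) -> str:
        names = []
        for hit in text.split(","):
            hit = hit.split("(")[0].split("*")[0].strip()
            if hit and hit not in names:
                names.append(hit)
        return ",".join(names)

    out = pd.DataFrame(
        {
            "junction": df["nSeqCDR3"],
            "junction_aa": df["aaSeqCDR3"],
            "v_call": df["allVHitsWithScore"].map(clean_calls),
            "j_call": df["allJHitsWithScore"].map(clean_calls),
            "duplicate_count": df["cloneCount"].astype(float).round().astype(int),
            "productive": [
                "T" if ("*" not in aa and "_" not in aa and aa) else "F"
                for aa in df["aaSeqCDR3"]
            ],
            "repertoire_id": Path(path).stem,
        }
    )
    tmp = Path(path).with_suffix(".airr.tsv")
    out.to_csv(tmp, sep="\t", index=False)
    try:
        return read_airr(tmp, **kwargs)
    finally:
        tmp.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# config + manifest
# ---------------------------------------------------------------------------


def _build_dataclass(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {context}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) and isinstance(value, dict):
            value = _build_dataclass(f.type, value, f"{context}.{f.name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_annotate_config(path: str | Path):
    """Load an annotation RunConfig from YAML, rejecting unknown keys."""
    from .annotate import AnnotateConfig
    from .functionality import FunctionalityConfig
    from .naming import NamingConfig
    from .rss import RssConfig

    data = yaml.safe_load(Path(path).read_text()) or {}
    sub = {"rss": RssConfig, "functionality": FunctionalityConfig, "naming": NamingConfig}
    kwargs = {}
    names = {f.name for f in dataclasses.fields(AnnotateConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {path}")
    for key, value in data.items():
        if key in sub and isinstance(value, dict):
            kwargs[key] = _build_dataclass(sub[key], value, key)
        else:
            kwargs[key] = value
    return AnnotateConfig(**kwargs)


def write_manifest(out_dir: str | Path, seed: int | None, params: dict) -> Path:
    """Record config, seed and version so a run can be reproduced."""
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "seed": seed, "params": params}
    out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return out
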