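"""IMGT-style nomenclature for annotated TR loci.

Names are assigned from genomic position (5'->3'), not discovery order:

* beta locus:   ``TRB{translocon}V{subgroup}-{n}`` for V genes (n runs
  5'->3' within the translocon and subgroup), ``TRBJ{n}``/``TRBD{n}``/
  ``TRBC{n}`` numbered across the whole locus;
* alpha/delta:  ``TRAV{subgroup}-{n}``, with the delta-preferential
  subgroup renamed via a ``/D`` marker (e.g. ``TRAV5/D1-3``); J, D and C
  genes are named per chain (TRAJ/TRAC vs TRDJ/TRDD/TRDC);
* gamma locus:  V, J and C genes of one mini-cluster share the cluster
  number (``TRGV{subgroup}-{k}``, ``TRGJ{k}``, ``TRGC{k}``); a missing J
  or C simply skips its number, and duplicated genes within a cluster
  receive distinct letter suffixes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .model import GeneSegment, LocusMap

log = logging.getLogger(__name__)


@dataclass
class NamingConfig:
    #: subgroup number -> delta designation index for alpha/delta loci
    delta_subgroups: dict[int, int] = field(default_factory=lambda: {5: 1})


def _ordered(segs: list[GeneSegment]) -> list[GeneSegment]:
    return sorted(segs, key=lambda s: (s.start, s.end))


def _suffix_duplicates(named: list[tuple[GeneSegment, str]]) -> None:
    by_base: dict[str, list[GeneSegment]] = defaultdict(list)
    for seg, base in named:
        by_base[base].append(seg)
    for base, members in by_base.items():
        if len(members) == 1:
            members[0].name = base
        else:
            for i, seg in enumerate(_ordered(members)):
                seg.name = f"{base}{chr(ord('A') + i)}"


def _name_beta(locus: LocusMap) -> list[GeneSegment]:
    refused: list[GeneSegment] = []
    counters: dict[tuple[int, int], int] = defaultdict(int)
    type_counters: dict[str, int] = defaultdict(int)
    for seg in _ordered(locus.segments):
        if seg.group_id is None:
            refused.append(seg)
            continue
        if seg.segment_type == "V":
            if seg.subgroup is None:
                refused.append(seg)
                continue
            counters[(seg.group_id, seg.subgroup)] += 1
            n = counters[(seg.group_id, seg.subgroup)]
            seg.name = f"TRB{seg.group_id}V{seg.subgroup}-{n}"
        else:
            type_counters[seg.segment_type] += 1
            seg.name = f"TRB{seg.segment_type}{type_counters[seg.segment_type]}"
    return refused


def _name_alpha_delta(locus: LocusMap, config: NamingConfig) -> list[GeneSegment]:
    refused: list[GeneSegment] = []
    v_counters: dict[int, int] = defaultdict(int)
    jdc_counters: dict[tuple[str, str], int] = defaultdict(int)
    totals: dict[tuple[str, str], int] = defaultdict(int)
    for seg in locus.segments:
        if seg.segment_type != "V":
            totals[(seg.chain or "A", seg.segment_type)] += 1
    for seg in _ordered(locus.segments):
        if seg.segment_type == "V":
            if seg.subgroup is None:
                refused.append(seg)
                continue
            v_counters[seg.subgroup] += 1
            n = v_counters[seg.subgroup]
            if seg.subgroup in config.delta_subgroups:
                marker = config.delta_subgroups[seg.subgroup]
                seg.name = f"TRAV{seg.subgroup}/D{marker}-{n}"
            else:
                seg.name = f"TRAV{seg.subgroup}-{n}"
        else:
            chain = seg.chain or "A"
            key = (chain, seg.segment_type)
            jdc_counters[key] += 1
            base = f"TR{chain}{seg.segment_type}"
            if totals[key] == 1:
                seg.name = base
            else:
                seg.name = f"{base}{jdc_counters[key]}"
    return refused


def _name_gamma(locus: LocusMap) -> list[GeneSegment]:
    refused: list[GeneSegment] = []
    named_v: list[tuple[GeneSegment, str]] = []
    named_jc: list[tuple[GeneSegment, str]] = []
    for seg in _ordered(locus.segments):
        if seg.group_id is None:
            refused.append(seg)
            continue
        if seg.segment_type == "V":
            if seg.subgroup is None:
                refused.append(seg)
                continue
            named_v.append((seg, f"TRGV{seg.subgroup}-{seg.group_id}"))
        else:
            named_jc.append((seg, f"TRG{seg.segment_type}{seg.group_id}"))
    _suffix_duplicates(named_v)
    _suffix_duplicates(named_jc)
    return refused


def refresh_minicluster_names(locus: LocusMap) -> None:
    """Rebuild mini-cluster member name lists after naming."""
    if not locus.miniclusters:
        return
    members: dict[int, list[str]] = defaultdict(list)
    complete: dict[int, bool] = {k: c for k, _, c in locus.miniclusters}
    for seg in locus.segments:
        if seg.group_id is not None and seg.name is not None:
            members[seg.group_id].append(seg.name)
    locus.miniclusters = [
        (k, members.get(k, []), complete[k]) for k, _, c in sorted(locus.miniclusters)
    ]


def assign_names(
    locus: LocusMap, chain: str, config: NamingConfig | None = None
) -> list[GeneSegment]:
    """Name every segment of ``locus``; returns segments naming refused.

    ``chain`` selects the scheme: 'B' (translocon), 'A/D' (shared
    alpha/delta translocon) or 'G' (mini-clusters).  Naming a V gene is
    refused (and reported) when its subgroup or group is unassigned.
    """
    config = config or NamingConfig()
    if chain == "B":
        refused = _name_beta(locus)
    elif chain in ("A/D", "A", "D"):
        refused = _name_alpha_delta(locus, config)
    elif chain == "G":
        refused = _name_gamma(locus)
        refresh_minicluster_names(locus)
    else:
        raise ValueError(f"unknown chain {chain!r}")
    for seg in refused:
        log.warning(
            "naming refused for %s segment at %d (unassigned subgroup/group)",
            seg.segment_type,
            seg.start,
        )
    names = [s.name for s in locus.segments if s.name is not None]
    if len(names) != len(set(names)):
        dupes = {n for n in names if names.count(n) > 1}
        raise ValueError(f"duplicate names assigned: {sorted(dupes)}")
    return refused
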