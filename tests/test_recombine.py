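"""V(D)J recombination simulator: junctions, productivity, repertoires."""

import numpy as np
import pytest
from Bio.Seq import Seq

from codtr.model import RepertoireSample
from codtr.recombine import (
    CloneSizeModel,
    RecombinationConfig,
    is_productive_cdr3,
    recombine_once,
    simulate_repertoire,
)
from codtr.simlocus import GermlineGene, GermlineSet

NO_EDITS = RecombinationConfig(p_trim=1.0, lambda_ins=0.0, selection_mode="none")


def _engineered_germline():
    """A custom in-frame germline: V ends exactly at its Cys codon and
    the J anchor sits at a frame-0 offset."""
    germline = GermlineSet()
    v_seq = "ATGGCAGAAGTT" + "TGT"  # ...Cys
    germline.add(GermlineGene("Vx", "V", "A", v_seq, cys_start=len(v_seq) - 3))
    j_seq = "GCAGAT" + "TTTGGAGCAGGA" + "GCAGCA"  # 6 nt, then F-G-A-G, tail
    germline.add(
        GermlineGene("Jx", "J", "A", j_seq, anchor_start=6, frame=0)
    )
    return germline


def test_zero_edit_junction_on_engineered_germline_is_identity():
    germline = _engineered_germline()
    rng = np.random.default_rng(0)
    clone = recombine_once(germline, "A", NO_EDITS, rng)
    assert clone.junction_nt == "ATGGCAGAAGTTTGT" + "GCAGATTTTGGAGCAGGAGCAGCA"
    assert clone.cdr3_nt == "TGT" + "GCAGAT" + "TTT"
    assert clone.cdr3_aa == "CADF"
    assert clone.productive
    assert clone.trims == {"v_3": 0, "j_5": 0}
    assert clone.insertions == {"vj": ""}


def test_cod_ad_germline_configuration_is_non_productive(cod_ad):
    """Both alpha and delta germline junctions are out of frame: without
    junctional insertions/deletions no rearrangement is productive."""
    rng = np.random.default_rng(1)
    for chain in ("A", "D"):
        for _ in range(40):
            clone = recombine_once(cod_ad.germline, chain, NO_EDITS, rng)
            assert not clone.productive
            assert len(clone.cdr3_nt) % 3 != 0


def test_single_nt_insertions_enumerate_to_frame_restoring_subset(cod_ad):
    """All four 1-nt insertions restore the alpha V-J frame; the
    productive ones are exactly those passing a translate oracle."""
    v = cod_ad.germline.pool("A", "V")[0]
    j = cod_ad.germline.pool("A", "J")[0]
    productive_bases = []
    for base in "ACGT":
        full = v.seq + base + j.seq
        anchor_pos = len(full) - (len(j.seq) - j.anchor_start)
        cdr3 = full[v.cys_start : anchor_pos + 3]
        assert len(cdr3) % 3 == 0  # frame restored by any single insertion
        aa = str(Seq(cdr3).translate())
        oracle = "*" not in aa and aa[0] == "C" and aa[-1] in "FW"
        assert is_productive_cdr3(cdr3) == oracle
        if oracle:
            productive_bases.append(base)
    # zero insertions: out of frame
    full0 = v.seq + j.seq
    anchor0 = len(full0) - (len(j.seq) - j.anchor_start)
    assert not is_productive_cdr3(full0[v.cys_start : anchor0 + 3])
    assert productive_bases  # at least one frame-restoring base is stop-free


def test_productive_flag_matches_translate_oracle_on_emitted_sample(cod_ad):
    sample, _ = simulate_repertoire(
        cod_ad.germline,
        "D",
        RecombinationConfig(selection_mode="none"),
        CloneSizeModel(n_clones=150, total_reads=4000, error_rate=0.002),
        seed=5,
    )
    assert any(not c.productive for c in sample.clonotypes)
    for c in sample.clonotypes:
        aa = str(Seq(c.cdr3_nt[: len(c.cdr3_nt) // 3 * 3]).translate())
        oracle = (
            len(c.cdr3_nt) % 3 == 0
            and len(c.cdr3_nt) >= 6
            and "*" not in aa
            and aa[0] == "C"
            and aa[-1] in "FW"
        )
        assert c.productive == oracle


def test_truth_recovery_without_noise(cod_b):
    """With zero sequencing error, every emitted clonotype maps exactly
    onto one truth record with identical V/J assignment."""
    sample, truth = simulate_repertoire(
        cod_b.germline,
        "B",
        RecombinationConfig(),
        CloneSizeModel(n_clones=200, total_reads=6000, error_rate=0.0),
        seed=6,
    )
    truth_map = truth.set_index("cdr3_nt")
    assert len(sample.clonotypes) == 200
    for c in sample.clonotypes:
        row = truth_map.loc[c.cdr3_nt]
        assert c.v_call == frozenset([row["v_id"]])
        assert c.j_call == frozenset([row["j_id"]])
        assert c.duplicate_count == row["duplicate_count"]
        assert c.productive == row["productive"]


def test_read_conservation_and_determinism(cod_g):
    model = CloneSizeModel(n_clones=100, total_reads=3000, error_rate=0.005)
    s1, t1 = simulate_repertoire(cod_g.germline, "G", seed=7, clone_model=model)
    s2, t2 = simulate_repertoire(cod_g.germline, "G", seed=7, clone_model=model)
    assert s1.total_reads == 3000
    assert int(t1["duplicate_count"].sum()) == 3000
    assert [
        (c.cdr3_nt, c.duplicate_count) for c in s1.clonotypes
    ] == [(c.cdr3_nt, c.duplicate_count) for c in s2.clonotypes]
    assert t1.equals(t2)


def test_tiny_germline_cannot_supply_requested_diversity():
    germline = _engineered_germline()
    with pytest.raises(RuntimeError, match="distinct"):
        simulate_repertoire(
            germline,
            "A",
            NO_EDITS,
            CloneSizeModel(n_clones=5, total_reads=100, error_rate=0.0),
            seed=8,
        )


def test_config_validation():
    with pytest.raises(ValueError):
        RecombinationConfig(p_trim=0.0)
    with pytest.raises(ValueError):
        CloneSizeModel(alpha=1.0)
    with pytest.raises(ValueError):
        CloneSizeModel(n_clones=10, total_reads=5)
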