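import pytest

from codtr.model import Clonotype, RepertoireSample
from codtr.simlocus import build_fixture_locus

PRESET_SEEDS = {"cod_AD": 11, "cod_B": 12, "cod_G": 13}


@pytest.fixture(scope="session")
def cod_ad():
    return build_fixture_locus("cod_AD", seed=PRESET_SEEDS["cod_AD"])


@pytest.fixture(scope="session")
def cod_b():
    return build_fixture_locus("cod_B", seed=PRESET_SEEDS["cod_B"])


@pytest.fixture(scope="session")
def cod_g():
    return build_fixture_locus("cod_G", seed=PRESET_SEEDS["cod_G"])


def make_sample(counts, sample_id="s", fish_id=None, aa=None, productive=None, **kw):
    """Build a small in-memory repertoire from read counts.

    ``counts`` may be a list of ints (CDR3s auto-generated) or a dict
    mapping aa CDR3 -> count.
    """
    if isinstance(counts, dict):
        items = list(counts.items())
    else:
        items = [(aa[i] if aa else f"CASS{i:03d}F", c) for i, c in enumerate(counts)]
    clonotypes = [
        Clonotype(
            cdr3_nt="TGT" + "GCA" * (len(a) - 2) + "TTT",
            cdr3_aa=a,
            v_call=frozenset([kw.get("v", "V1")]),
            j_call=frozenset([kw.get("j", "J1")]),
            duplicate_count=c,
            productive=True if productive is None else productive[i],
        )
        for i, (a, c) in enumerate(items)
    ]
    return RepertoireSample(sample_id=sample_id, clonotypes=clonotypes, fish_id=fish_id)
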