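"""Repertoire statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from conftest import make_sample
from hypothesis import given, settings
from hypothesis import strategies as st

from codtr import stats as cs
from codtr.model import Clonotype, RepertoireSample
from codtr.recombine import CloneSizeModel, simulate_repertoire

# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def test_filter_read_threshold_is_strict_less_than():
    sample = make_sample([4, 5, 6])
    kept = cs.filter_clonotypes(sample, min_reads=5)
    assert [c.duplicate_count for c in kept.clonotypes] == [5, 6]


def test_filter_removes_non_productive_and_is_idempotent():
    sample = make_sample([9, 9, 9], productive=[True, False, True])
    once = cs.filter_clonotypes(sample)
    twice = cs.filter_clonotypes(once)
    assert len(once.clonotypes) == 2
    assert [c.cdr3_aa for c in once.clonotypes] == [c.cdr3_aa for c in twice.clonotypes]


def test_filter_empty_table():
    assert cs.filter_clonotypes(make_sample([])).clonotypes == []


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------


def test_rarefaction_full_depth_is_exact_with_zero_variance():
    sample = make_sample([7, 3, 2])
    df = cs.rarefaction(sample, [12], n_reps=5, seed=0)
    assert df["mean_unique"].iloc[0] == 3.0
    assert df["sd_unique"].iloc[0] == 0.0


def test_rarefaction_depth_one_of_singletons():
    sample = make_sample([1, 1, 1])
    df = cs.rarefaction(sample, [1], n_reps=10, seed=0)
    assert df["mean_unique"].iloc[0] == 1.0


def test_rarefaction_matches_hypergeometric_expectation():
    # counts (5,5), depth 2: E[unique] = 2 - 2*C(5,2)/C(10,2) = 14/9
    sample = make_sample([5, 5])
    n_reps = 4000
    df = cs.rarefaction(sample, [2], n_reps=n_reps, seed=1)
    expected = 2 - 2 * math.comb(5, 2) / math.comb(10, 2)
    assert expected == pytest.approx(1.5556, abs=1e-4)
    se = math.sqrt(0.25 / n_reps)  # unique is 1 or 2: Bernoulli + 1
    assert abs(df["mean_unique"].iloc[0] - expected) < 3 * se


def test_rarefaction_depth_beyond_total_is_error():
    with pytest.raises(ValueError):
        cs.rarefaction(make_sample([2, 2]), [5])


# ---------------------------------------------------------------------------
# D50 / Shannon
# ---------------------------------------------------------------------------


def _d50_oracle(counts):
    ordered = sorted(counts, reverse=True)
    half = sum(counts) / 2
    for k in range(1, len(ordered) + 1):
        if sum(ordered[:k]) >= half:
            return k
    raise AssertionError


@pytest.mark.parametrize(
    "counts,expected_count,expected_prop",
    [([10] * 10, 5, 0.5), ([50, 30, 10, 10], 1, 0.25), ([42], 1, 1.0)],
)
def test_d50_examples(counts, expected_count, expected_prop):
    count, prop = cs.d50(make_sample(counts))
    assert count == expected_count
    assert prop == pytest.approx(expected_prop)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=20))
def test_d50_matches_prefix_oracle(counts):
    count, prop = cs.d50(make_sample(counts))
    assert count == _d50_oracle(counts)
    assert prop == count / len(counts)


@pytest.mark.parametrize(
    "counts,base,expected",
    [([1] * 8, 2, 3.0), ([5], 2, 0.0), ([3, 1], 2, 0.8113)],
)
def test_shannon_examples(counts, base, expected):
    assert cs.shannon(make_sample(counts), base=base) == pytest.approx(expected, abs=1e-4)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=20))
def test_shannon_matches_direct_formula(counts):
    total = sum(counts)
    expected = -sum((c / total) * math.log2(c / total) for c in counts)
    assert cs.shannon(make_sample(counts)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# CDR3 lengths
# ---------------------------------------------------------------------------


def test_cdr3_length_mean_examples():
    sample = make_sample({"C" + "A" * 11 + "F": 3, "C" + "A" * 11 + "W": 7})
    _, mean = cs.cdr3_length_stats(sample)
    assert mean == 13.0
    sample2 = make_sample({"C" + "A" * 8 + "F": 1, "C" + "A" * 12 + "F": 9})
    _, mean2 = cs.cdr3_length_stats(sample2)  # unique-weighted
    assert mean2 == 12.0
    _, mean_reads = cs.cdr3_length_stats(sample2, weighting="reads")
    assert mean_reads == pytest.approx(round((10 * 1 + 14 * 9) / 10, 1))


def test_cdr3_length_oracle_on_simulated_sample(cod_g):
    sample, _ = simulate_repertoire(
        cod_g.germline, "G", seed=4,
        clone_model=CloneSizeModel(n_clones=100, total_reads=2000, error_rate=0.0),
    )
    hist, mean = cs.cdr3_length_stats(sample)
    lengths = [len(c.cdr3_aa) for c in sample.clonotypes]
    assert mean == round(sum(lengths) / len(lengths), 1)
    assert int(hist.sum()) == len(lengths)


# ---------------------------------------------------------------------------
# V usage + correlation
# ---------------------------------------------------------------------------


def _usage_sample(calls_counts):
    clonotypes = [
        Clonotype(
            cdr3_nt="TGTTTT", cdr3_aa=f"CF{i}", v_call=frozenset(calls),
            j_call=frozenset(["J1"]), duplicate_count=n, productive=True,
        )
        for i, (calls, n) in enumerate(calls_counts)
    ]
    return RepertoireSample(sample_id="u", clonotypes=clonotypes)


def test_v_usage_single_gene_and_ambiguity_handling():
    sample = _usage_sample([(["V1"], 5), (["V1"], 2), (["V1", "V2"], 9)])
    freq, dropped = cs.v_usage(sample, ["V1", "V2", "V3"])
    assert freq["V1"] == 1.0 and freq["V2"] == 0.0 and freq["V3"] == 0.0
    assert dropped == pytest.approx(1 / 3)


def test_v_usage_matches_hand_tally_with_read_weighting():
    sample = _usage_sample([(["V1"], 6), (["V2"], 2), (["V2"], 2)])
    freq, _ = cs.v_usage(sample, ["V1", "V2"], weighting="reads")
    assert freq["V1"] == pytest.approx(0.6)
    assert freq["V2"] == pytest.approx(0.4)


def test_v_usage_unknown_gene_is_error():
    sample = _usage_sample([(["V9"], 5)])
    with pytest.raises(ValueError, match="V9"):
        cs.v_usage(sample, ["V1"])


def test_usage_correlation_examples_and_oracle():
    a = pd.Series([0.5, 0.3, 0.2], index=list("xyz"))
    b = pd.Series([1.0, 0.0, 0.0], index=list("xyz"))
    corr, mean = cs.usage_correlation([a, a])
    assert corr.iloc[0, 1] == pytest.approx(1.0) and mean == pytest.approx(1.0)
    two_a = pd.Series([1.0, 0.0], index=list("xy"))
    two_b = pd.Series([0.0, 1.0], index=list("xy"))
    _, mean2 = cs.usage_correlation([two_a, two_b])
    assert mean2 == pytest.approx(-1.0)
    c = pd.Series([0.1, 0.4, 0.5], index=list("xyz"))
    corr3, mean3 = cs.usage_correlation([a, b, c])
    for u, v, (i, j) in [(a, b, (0, 1)), (a, c, (0, 2)), (b, c, (1, 2))]:
        expected = np.corrcoef(u.to_numpy(), v.to_numpy())[0, 1]
        assert corr3.iloc[i, j] == pytest.approx(expected)
    assert mean3 == pytest.approx(
        np.mean([corr3.iloc[0, 1], corr3.iloc[0, 2], corr3.iloc[1, 2]])
    )


def test_usage_correlation_zero_variance_reported_missing():
    flat = pd.Series([0.5, 0.5], index=list("xy"))
    var = pd.Series([0.9, 0.1], index=list("xy"))
    corr, mean = cs.usage_correlation([flat, var])
    assert np.isnan(corr.iloc[0, 1]) and np.isnan(mean)


# ---------------------------------------------------------------------------
# overlap / publicness
# ---------------------------------------------------------------------------


def _tau_b_oracle(x, y):
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - _ties(x)) * (n0 - _ties(y)))


def _ties(v):
    from collections import Counter

    return sum(m * (m - 1) / 2 for m in Counter(v).values())


def test_overlap_identical_samples():
    s = make_sample([10, 7, 3])
    res = cs.overlap(s, s)
    assert res.n_shared == 3 and res.n_union == 3
    assert res.kendall_tau == pytest.approx(1.0)


def test_overlap_reversed_ranks():
    aa = [f"CASS{i}F" for i in range(4)]
    a = make_sample(dict(zip(aa, [40, 30, 20, 10])))
    b = make_sample(dict(zip(aa, [10, 20, 30, 40])))
    res = cs.overlap(a, b)
    assert res.kendall_tau == pytest.approx(-1.0)


def test_overlap_tau_matches_enumeration_oracle():
    aa = [f"CASS{i}F" for i in range(5)]
    xa, xb = [12, 5, 30, 2, 9], [3, 18, 7, 25, 4]
    res = cs.overlap(make_sample(dict(zip(aa, xa))), make_sample(dict(zip(aa, xb))))
    # counts are keyed by sorted aa, realign the oracle the same way
    order = sorted(range(5), key=lambda i: aa[i])
    ox = [xa[i] for i in order]
    oy = [xb[i] for i in order]
    assert res.kendall_tau == pytest.approx(_tau_b_oracle(ox, oy))


def test_overlap_too_few_shared_is_missing():
    a = make_sample({"CAAF": 5, "CBBF": 5})
    b = make_sample({"CAAF": 5, "CCCF": 5})
    res = cs.overlap(a, b)
    assert res.n_shared == 1 and res.kendall_tau is None


def test_publicness_disjoint_and_fully_shared():
    a = make_sample({"CAAF": 1, "CABF": 1}, sample_id="f1", fish_id="f1")
    b = make_sample({"CBAF": 1, "CBBF": 1}, sample_id="f2", fish_id="f2")
    _, props = cs.publicness([a, b])
    assert (props["shared_by_1"] == 1.0).all()
    c = make_sample({"CAAF": 1, "CABF": 1}, sample_id="f3", fish_id="f3")
    _, props2 = cs.publicness([a, c])
    assert (props2["shared_by_2"] == 1.0).all()


def test_publicness_hand_tally_three_fish():
    common = "CXXF"
    samples = [
        make_sample({common: 1, f"CA{i}F": 1, f"CB{i}F": 1}, sample_id=f"f{i}", fish_id=f"f{i}")
        for i in range(3)
    ]
    level, props = cs.publicness(samples)
    assert level[common] == 3
    for i in range(3):
        assert props.loc[f"f{i}", "shared_by_3"] == pytest.approx(1 / 3)
        assert props.loc[f"f{i}", "shared_by_1"] == pytest.approx(2 / 3)
    assert props.sum(axis=1).round(9).eq(1.0).all()


def test_publicness_duplicate_fish_rejected():
    a = make_sample({"CAAF": 1}, sample_id="s1", fish_id="f1")
    b = make_sample({"CABF": 1}, sample_id="s2", fish_id="f1")
    with pytest.raises(ValueError, match="fish"):
        cs.publicness([a, b])


# ---------------------------------------------------------------------------
# bounds / inter-translocon
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "observed,fraction,expected_upper",
    [(4422, 0.15, 29480), (852, 0.15, 5680), (100, 1.0, 100)],
)
def test_repertoire_bounds_worked_examples(observed, fraction, expected_upper):
    lower, upper = cs.repertoire_bounds(observed, fraction)
    assert lower == observed and upper == expected_upper


def test_repertoire_bounds_monotone_in_fraction():
    uppers = [cs.repertoire_bounds(500, f)[1] for f in (0.5, 0.25, 0.1)]
    assert uppers == sorted(uppers)
    with pytest.raises(ValueError):
        cs.repertoire_bounds(10, 0.0)
    with pytest.raises(ValueError):
        cs.repertoire_bounds(10, 1.5)


def _it_sample(rows):
    clonotypes = [
        Clonotype(
            cdr3_nt="TGTTTT", cdr3_aa=f"C{i}F", v_call=frozenset(v),
            j_call=frozenset(j), duplicate_count=2, productive=True,
        )
        for i, (v, j) in enumerate(rows)
    ]
    return RepertoireSample(sample_id="it", clonotypes=clonotypes)


def test_intertranslocon_events_and_denominators():
    tmap = {"V1": 1, "V2": 2, "J1": 1, "J2": 2}
    sample = _it_sample(
        [
            (["V1"], ["J2"]),        # event
            (["V1"], ["J1"]),        # same translocon
            (["V2"], ["J1", "J2"]),  # ambiguous J: excluded, in denominator
        ]
    )
    res = cs.intertranslocon_events(sample, tmap)
    assert res.n_events == 1
    assert res.n_total == 3 and res.n_unambiguous == 2
    assert res.fraction_of_total == pytest.approx(1 / 3)
    assert res.fraction_of_unambiguous == pytest.approx(1 / 2)
    assert res.matrix.loc[1, 2] == 1 and res.matrix.loc[1, 1] == 1


def test_intertranslocon_missing_id_is_error():
    sample = _it_sample([(["V9"], ["J1"])])
    with pytest.raises(ValueError, match="V9"):
        cs.intertranslocon_events(sample, {"J1": 1})


# ---------------------------------------------------------------------------
# simulator round trip
# ---------------------------------------------------------------------------


def test_statistics_match_truth_table_without_noise(cod_b):
    sample, truth = simulate_repertoire(
        cod_b.germline, "B", seed=9,
        clone_model=CloneSizeModel(n_clones=300, total_reads=9000, error_rate=0.0),
    )
    count, prop = cs.d50(sample)
    truth_counts = truth["duplicate_count"].tolist()
    assert count == _d50_oracle(truth_counts)
    total = sum(truth_counts)
    expected_shannon = -sum(
        (c / total) * math.log2(c / total) for c in truth_counts
    )
    assert cs.shannon(sample) == pytest.approx(expected_shannon)
    assert sample.unique_nt == len(truth)
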