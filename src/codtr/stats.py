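"""Expressed-repertoire statistics over CDR3-collapsed clonotype tables.

Implements the standard AIRR-style descriptive statistics: read/productivity
filtering, rarefaction, D50, Shannon entropy, CDR3 length profiles, V-gene
usage and its cross-sample correlation, replicate overlap with Kendall
tau-b, public/private sharedness across fish, whole-organ repertoire-size
bounds from the sampled organ fraction, and inter-translocon V-J pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .model import Clonotype, RepertoireSample


def filter_clonotypes(
    sample: RepertoireSample, min_reads: int = 5, productive_only: bool = True
) -> RepertoireSample:
    """Drop clonotypes below ``min_reads`` reads (strictly less) and,
    optionally, non-productive ones.  Order preserved; idempotent."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    kept = [
        c
        for c in sample.clonotypes
        if c.duplicate_count >= min_reads and (c.productive or not productive_only)
    ]
    return RepertoireSample(
        sample_id=sample.sample_id,
        clonotypes=kept,
        fish_id=sample.fish_id,
        chain=sample.chain,
        replicate=sample.replicate,
        total_mapped_reads=sample.total_mapped_reads,
        sampling_fraction=sample.sampling_fraction,
    )


def _aa_read_counts(sample: RepertoireSample) -> pd.Series:
    counts: dict[str, int] = {}
    for c in sample.clonotypes:
        counts[c.cdr3_aa] = counts.get(c.cdr3_aa, 0) + c.duplicate_count
    return pd.Series(counts, dtype=np.int64).sort_index()


def rarefaction(
    sample: RepertoireSample,
    depths: Iterable[int],
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean unique aa-CDR3 count at each subsampled read depth.

    Reads are subsampled without replacement from the read-expanded
    clonotype multiset (a multivariate hypergeometric draw per
    replicate).  At full depth the count equals the sample's unique
    aa-CDR3 count with zero variance.
    """
    counts = _aa_read_counts(sample)
    total = int(counts.sum())
    depths = list(depths)
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds total reads ({total})")
    rng = np.random.default_rng(seed)
    rows = []
    arr = counts.to_numpy()
    for depth in depths:
        uniques = [
            int(np.count_nonzero(rng.multivariate_hypergeometric(arr, depth)))
            for _ in range(n_reps)
        ]
        rows.append(
            {
                "depth": depth,
                "mean_unique": float(np.mean(uniques)),
                "sd_unique": float(np.std(uniques, ddof=1)) if n_reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def d50(sample: RepertoireSample) -> tuple[int, float]:
    """Minimal number of top clonotypes covering half the reads, and the
    same as a proportion of unique clonotypes.

    Ties in read count break on aa-CDR3 lexicographic order, so the
    result is deterministic.
    """
    if not sample.clonotypes:
        raise ValueError("empty sample")
    ordered = sorted(
        sample.clonotypes, key=lambda c: (-c.duplicate_count, c.cdr3_aa)
    )
    half = sum(c.duplicate_count for c in ordered) / 2.0
    acc = 0
    for k, c in enumerate(ordered, start=1):
        acc += c.duplicate_count
        if acc >= half:
            return k, k / len(ordered)
    raise AssertionError("unreachable")


def shannon(sample: RepertoireSample, base: float = 2.0) -> float:
    """Shannon entropy of clonotype read frequencies."""
    if not sample.clonotypes:
        raise ValueError("empty sample")
    counts = np.array([c.duplicate_count for c in sample.clonotypes], dtype=float)
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def cdr3_length_stats(
    sample: RepertoireSample, weighting: str = "clonotypes"
) -> tuple[pd.Series, float]:
    """aa-CDR3 length histogram and mean (one decimal).

    ``weighting`` 'clonotypes' counts each unique clonotype once;
    'reads' weights by duplicate_count.
    """
    if not sample.clonotypes:
        raise ValueError("empty sample")
    if weighting not in ("clonotypes", "reads"):
        raise ValueError(f"bad weighting {weighting!r}")
    lengths = np.array([len(c.cdr3_aa) for c in sample.clonotypes])
    weights = (
        np.ones_like(lengths)
        if weighting == "clonotypes"
        else np.array([c.duplicate_count for c in sample.clonotypes])
    )
    hist = pd.Series(weights).groupby(pd.Series(lengths)).sum().sort_index()
    hist.index.name = "length_aa"
    mean = float(np.average(lengths, weights=weights))
    return hist, round(mean, 1)


def v_usage(
    sample: RepertoireSample,
    universe: Iterable[str],
    drop_ambiguous: bool = True,
    weighting: str = "clonotypes",
) -> tuple[pd.Series, float]:
    """V-gene frequency vector over ``universe`` plus the fraction of
    clonotypes dropped as ambiguous.

    Ambiguously assigned clonotypes (more than one V call) are removed
    before tallying, mirroring standard repertoire practice.
    """
    universe = list(universe)
    if weighting not in ("clonotypes", "reads"):
        raise ValueError(f"bad weighting {weighting!r}")
    known = set(universe)
    tally = pd.Series(0.0, index=universe)
    n_total = len(sample.clonotypes)
    n_dropped = 0
    for c in sample.clonotypes:
        unknown = c.v_call - known
        if unknown:
            raise ValueError(f"V call(s) outside gene universe: {sorted(unknown)}")
        if len(c.v_call) > 1:
            if drop_ambiguous:
                n_dropped += 1
                continue
            w = (1 if weighting == "clonotypes" else c.duplicate_count) / len(c.v_call)
            for name in c.v_call:
                tally[name] += w
            continue
        (name,) = c.v_call
        tally[name] += 1 if weighting == "clonotypes" else c.duplicate_count
    total = tally.sum()
    freq = tally / total if total > 0 else tally
    dropped_fraction = n_dropped / n_total if n_total else 0.0
    return freq, dropped_fraction


def usage_correlation(
    usage_vectors: list[pd.Series], method: str = "pearson"
) -> tuple[pd.DataFrame, float]:
    """Pairwise correlation matrix of usage vectors and the mean over
    distinct pairs.  Zero-variance vectors yield undefined (NaN)
    correlations, excluded from the mean."""
    if len(usage_vectors) < 2:
        raise ValueError("need at least two usage vectors")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"bad method {method!r}")
    index = usage_vectors[0].index
    mat = pd.DataFrame(
        {i: v.reindex(index) for i, v in enumerate(usage_vectors)}
    )
    corr = mat.corr(method=method)
    n = len(usage_vectors)
    off = [corr.iloc[i, j] for i in range(n) for j in range(i + 1, n)]
    valid = [x for x in off if not np.isnan(x)]
    mean = float(np.mean(valid)) if valid else float("nan")
    return corr, mean


@dataclass
class OverlapResult:
    shared: set[str]
    n_shared: int
    n_union: int
    n_unique_a: int
    n_unique_b: int
    kendall_tau: Optional[float]
    p_value: Optional[float]


def overlap(a: RepertoireSample, b: RepertoireSample) -> OverlapResult:
    """Replicate overlap at the aa-CDR3 level with rank correlation.

    Kendall tau-b is computed on the paired read counts of the shared
    CDR3s; the p-value uses exact enumeration for n <= 8 shared CDR3s
    without ties and the normal approximation otherwise.
    """
    if a.chain is not None and b.chain is not None and a.chain != b.chain:
        raise ValueError("samples must be of the same chain")
    ca, cb = _aa_read_counts(a), _aa_read_counts(b)
    shared = sorted(set(ca.index) & set(cb.index))
    union = set(ca.index) | set(cb.index)
    tau = p = None
    if len(shared) >= 2:
        x = ca.loc[shared].to_numpy()
        y = cb.loc[shared].to_numpy()
        no_ties = len(set(x)) == len(x) and len(set(y)) == len(y)
        method = "exact" if (len(shared) <= 8 and no_ties) else "asymptotic"
        res = sp_stats.kendalltau(x, y, variant="b", method=method)
        tau, p = float(res.statistic), float(res.pvalue)
    return OverlapResult(
        shared=set(shared),
        n_shared=len(shared),
        n_union=len(union),
        n_unique_a=len(ca),
        n_unique_b=len(cb),
        kendall_tau=tau,
        p_value=p,
    )


def publicness(
    samples: list[RepertoireSample],
) -> tuple[dict[str, int], pd.DataFrame]:
    """Sharing level per aa CDR3 and per-sample sharedness proportions.

    The sharing level of a CDR3 is the number of distinct fish whose
    sample contains it.  Each sample's proportions (over its unique aa
    CDR3s) of private, shared-by-2, ..., shared-by-all sum to one.
    Requires one sample per fish.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    fish = [s.fish_id if s.fish_id is not None else s.sample_id for s in samples]
    if len(set(fish)) != len(fish):
        raise ValueError("duplicate fish_id; select one replicate per fish first")
    sets = [{c.cdr3_aa for c in s.clonotypes} for s in samples]
    level: dict[str, int] = {}
    for aa_set in sets:
        for aa in aa_set:
            level[aa] = level.get(aa, 0) + 1
    n = len(samples)
    rows = []
    for s, aa_set in zip(samples, sets):
        counts = {k: 0 for k in range(1, n + 1)}
        for aa in aa_set:
            counts[level[aa]] += 1
        total = len(aa_set)
        rows.append(
            {
                "sample_id": s.sample_id,
                **{
                    f"shared_by_{k}": (counts[k] / total if total else 0.0)
                    for k in range(1, n + 1)
                },
            }
        )
    return level, pd.DataFrame(rows).set_index("sample_id")


def repertoire_bounds(observed_unique: int, sampling_fraction: float) -> tuple[int, int]:
    """Lower and upper bounds on whole-organ unique diversity.

    The observed unique count is the lower bound (everything unseen could
    duplicate what was seen); the upper bound assumes the unsampled organ
    fraction holds entirely novel receptors at the same density:
    floor(observed / fraction).
    """
    if not 0 < sampling_fraction <= 1:
        raise ValueError("sampling_fraction must be in (0, 1]")
    if observed_unique < 0:
        raise ValueError("observed_unique must be >= 0")
    return observed_unique, math.floor(observed_unique / sampling_fraction)


@dataclass
class IntertransloconResult:
    n_events: int
    n_total: int
    n_unambiguous: int
    fraction_of_total: float
    fraction_of_unambiguous: float
    matrix: pd.DataFrame = field(repr=False)


def intertranslocon_events(
    sample: RepertoireSample, translocon_of: dict[str, int]
) -> IntertransloconResult:
    """Count V-J pairings that cross translocons.

    Only clonotypes with a single (unambiguous) V and J call are
    eligible; an event is a clonotype whose V and J lie in different
    translocons.  ``fraction_of_total`` divides by all clonotypes,
    ``fraction_of_unambiguous`` by the eligible subset only.
    """
    ts = sorted(set(translocon_of.values()))
    matrix = pd.DataFrame(0, index=ts, columns=ts)
    n_events = n_unamb = 0
    for c in sample.clonotypes:
        if len(c.v_call) != 1 or len(c.j_call) != 1:
            continue
        (v,), (j,) = c.v_call, c.j_call
        for name in (v, j):
            if name not in translocon_of:
                raise ValueError(f"gene {name!r} has no translocon id")
        n_unamb += 1
        tv, tj = translocon_of[v], translocon_of[j]
        matrix.loc[tv, tj] += 1
        if tv != tj:
            n_events += 1
    n_total = len(sample.clonotypes)
    return IntertransloconResult(
        n_events=n_events,
        n_total=n_total,
        n_unambiguous=n_unamb,
        fraction_of_total=n_events / n_total if n_total else 0.0,
        fraction_of_unambiguous=n_events / n_unamb if n_unamb else 0.0,
        matrix=matrix,
    )


@dataclass
class DiversityReport:
    unique_nt: int
    unique_aa: int
    d50_count: int
    d50_proportion: float
    shannon: float
    functional_fraction: float
    cdr3_aa_mean: float
    lower_bound: int
    upper_bound: int


def diversity_report(sample: RepertoireSample, base: float = 2.0) -> DiversityReport:
    """One-stop summary of a (typically pre-filtered) sample."""
    count, proportion = d50(sample)
    _, mean_len = cdr3_length_stats(sample)
    lower, upper = repertoire_bounds(sample.unique_nt, sample.sampling_fraction)
    n_func = sum(c.productive for c in sample.clonotypes)
    return DiversityReport(
        unique_nt=sample.unique_nt,
        unique_aa=sample.unique_aa,
        d50_count=count,
        d50_proportion=proportion,
        shannon=shannon(sample, base),
        functional_fraction=n_func / len(sample.clonotypes),
        cdr3_aa_mean=mean_len,
        lower_bound=lower,
        upper_bound=upper,
    )


def select_replicates(samples: list[RepertoireSample]) -> list[RepertoireSample]:
    """Keep one sample per fish: the replicate with more total reads."""
    best: dict[str, RepertoireSample] = {}
    for s in samples:
        key = s.fish_id if s.fish_id is not None else s.sample_id
        if key not in best or s.total_reads > best[key].total_reads:
            best[key] = s
    return list(best.values())
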