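"""V(D)J recombination and clonal-repertoire simulation.

A rearrangement picks germline segments (V-J for alpha/gamma, V-D-J for
beta/delta), trims each coding end by geometric draws, inserts
Poisson-many non-templated nucleotides at each junction, and extracts
the CDR3 between the V gene's 2nd-CYS codon and the J gene's F/W
anchor (both inclusive).  A rearrangement is productive when that CDR3
is in frame, stop-free, and retains both anchors.

A repertoire assigns power-law (Zipf) read counts to distinct
rearrangements — the rank-abundance shape under which a few percent of
top clonotypes cover half of the reads — and can corrupt individual
reads with substitution errors before CDR3-level collapse, so that the
downstream minimum-read filter has realistic low-count artefacts to
remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .functionality import translate_frame
from .model import Clonotype, RepertoireSample, SimulatedClonotype
from .simlocus import GermlineGene, GermlineSet

#: chains that use a D segment
VDJ_CHAINS = ("B", "D")


@dataclass
class RecombinationConfig:
    p_trim: float = 0.35  # geometric success prob; mean trim (1-p)/p
    lambda_ins: float = 4.0  # Poisson mean inserted nt per junction
    selection_mode: str = "productive_only"  # or "none"
    max_retries: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.p_trim <= 1:
            raise ValueError("p_trim must be in (0, 1]")
        if self.lambda_ins < 0:
            raise ValueError("lambda_ins must be >= 0")
        if self.selection_mode not in ("none", "productive_only"):
            raise ValueError(f"bad selection_mode {self.selection_mode!r}")


@dataclass
class CloneSizeModel:
    """Zipf rank-abundance: clone i gets weight (i+1)^-alpha."""

    n_clones: int = 1500
    alpha: float = 1.1
    total_reads: int = 100_000
    error_rate: float = 0.001  # per-nt substitution probability per read

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.n_clones < 1 or self.total_reads < self.n_clones:
            raise ValueError("need total_reads >= n_clones >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def is_productive_cdr3(cdr3_nt: str) -> bool:
    """Frame-intact, stop-free CDR3 with Cys and F/W anchors retained."""
    if len(cdr3_nt) % 3 != 0 or len(cdr3_nt) < 6:
        return False
    aa = translate_frame(cdr3_nt, 0)
    return "*" not in aa and aa[0] == "C" and aa[-1] in "FW"


def _geom_trim(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p)) - 1


def _insert(rng: np.random.Generator, lam: float) -> str:
    n = int(rng.poisson(lam))
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def _attempt(
    germline: GermlineSet, chain: str, config: RecombinationConfig, rng: np.random.Generator
) -> SimulatedClonotype | None:
    vs, js = germline.pool(chain, "V"), germline.pool(chain, "J")
    if not vs or not js:
        raise ValueError(f"chain {chain!r} missing V or J germline genes")
    v = vs[rng.integers(0, len(vs))]
    j = js[rng.integers(0, len(js))]
    use_d = chain in VDJ_CHAINS
    d: GermlineGene | None = None
    if use_d:
        ds = germline.pool(chain, "D")
        if not ds:
            raise ValueError(f"chain {chain!r} requires a D gene pool")
        d = ds[rng.integers(0, len(ds))]

    max_v_trim = len(v.seq) - (v.cys_start + 3)
    v_trim = _geom_trim(rng, config.p_trim)
    j_trim = _geom_trim(rng, config.p_trim)
    if v_trim > max_v_trim or j_trim > j.anchor_start:
        return None
    trims = {"v_3": v_trim, "j_5": j_trim}
    insertions: dict[str, str] = {}
    middle = ""
    if use_d and d is not None:
        d5 = _geom_trim(rng, config.p_trim)
        d3 = _geom_trim(rng, config.p_trim)
        if d5 + d3 > len(d.seq):
            return None
        trims.update({"d_5": d5, "d_3": d3})
        core = d.seq[d5 : len(d.seq) - d3]
        ins_vd = _insert(rng, config.lambda_ins)
        ins_dj = _insert(rng, config.lambda_ins)
        insertions = {"vd": ins_vd, "dj": ins_dj}
        middle = ins_vd + core + ins_dj
    else:
        ins_vj = _insert(rng, config.lambda_ins)
        insertions = {"vj": ins_vj}
        middle = ins_vj

    full = v.seq[: len(v.seq) - v_trim] + middle + j.seq[j_trim:]
    anchor_pos = len(full) - (len(j.seq) - j.anchor_start)
    cdr3_nt = full[v.cys_start : anchor_pos + 3]
    productive = is_productive_cdr3(cdr3_nt)
    cdr3_aa = translate_frame(cdr3_nt, 0)
    return SimulatedClonotype(
        v_id=v.name,
        j_id=j.name,
        d_id=d.name if d is not None else None,
        junction_nt=full,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        productive=productive,
        trims=trims,
        insertions=insertions,
    )


def recombine_once(
    germline: GermlineSet,
    chain: str,
    config: RecombinationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedClonotype:
    """Simulate one rearrangement; honours ``selection_mode``.

    Trim draws exceeding the available segment length are redrawn a
    bounded number of times before raising.
    """
    config = config or RecombinationConfig()
    rng = rng if rng is not None else np.random.default_rng()
    for _ in range(config.max_retries):
        clone = _attempt(germline, chain, config, rng)
        if clone is None:
            continue
        if config.selection_mode == "productive_only" and not clone.productive:
            continue
        return clone
    raise RuntimeError(
        f"no admissible rearrangement for chain {chain} in "
        f"{config.max_retries} attempts"
    )


def _allocate_reads(
    n_clones: int, alpha: float, total_reads: int
) -> np.ndarray:
    """Zipf largest-remainder allocation; every clone gets >= 1 read and
    the counts sum exactly to ``total_reads``."""
    ranks = np.arange(1, n_clones + 1, dtype=float)
    w = ranks ** (-alpha)
    w /= w.sum()
    spare = total_reads - n_clones
    exact = spare * w
    counts = np.ones(n_clones, dtype=np.int64) + np.floor(exact).astype(np.int64)
    remainder = spare - int(np.floor(exact).sum())
    if remainder > 0:
        order = np.argsort(-(exact - np.floor(exact)), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alt[rng.integers(0, 3)] + seq[pos + 1 :]


def simulate_repertoire(
    germline: GermlineSet,
    chain: str,
    config: RecombinationConfig | None = None,
    clone_model: CloneSizeModel | None = None,
    seed: int = 0,
    sample_id: str = "sim",
    fish_id: str | None = None,
    replicate: str | None = None,
) -> tuple[RepertoireSample, pd.DataFrame]:
    """Simulate a clonal repertoire with hidden ground truth.

    Returns the CDR3-collapsed sample (after read-level substitution
    noise) and the truth table of the drawn rearrangements.  The sum of
    emitted duplicate_count equals ``clone_model.total_reads``.
    """
    config = config or RecombinationConfig()
    clone_model = clone_model or CloneSizeModel()
    rng = np.random.default_rng(seed)

    clones: list[SimulatedClonotype] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = clone_model.n_clones * 200
    while len(clones) < clone_model.n_clones:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {clone_model.n_clones} distinct CDR3s "
                f"in {max_attempts} attempts (germline too small?)"
            )
        clone = recombine_once(germline, chain, config, rng)
        if clone.cdr3_nt in seen:
            continue
        seen.add(clone.cdr3_nt)
        clones.append(clone)

    counts = _allocate_reads(
        clone_model.n_clones, clone_model.alpha, clone_model.total_reads
    )

    # read-level substitution noise applied before CDR3 collapse
    table: dict[str, dict] = {}
    for clone, count in zip(clones, counts):
        count = int(count)
        n_err = 0
        if clone_model.error_rate > 0:
            p_read = 1.0 - (1.0 - clone_model.error_rate) ** len(clone.cdr3_nt)
            n_err = int(rng.binomial(count, p_read))
        keep = count - n_err
        if keep > 0:
            rec = table.setdefault(
                clone.cdr3_nt,
                {
                    "v": clone.v_id,
                    "j": clone.j_id,
                    "count": 0,
                    "productive": clone.productive,
                },
            )
            rec["count"] += keep
        for _ in range(n_err):
            pos = int(rng.integers(0, len(clone.cdr3_nt)))
            variant = _substitute(clone.cdr3_nt, pos, rng)
            rec = table.setdefault(
                variant,
                {
                    "v": clone.v_id,
                    "j": clone.j_id,
                    "count": 0,
                    "productive": is_productive_cdr3(variant),
                },
            )
            rec["count"] += 1

    clonotypes = [
        Clonotype(
            cdr3_nt=nt,
            cdr3_aa=translate_frame(nt, 0),
            v_call=frozenset([rec["v"]]),
            j_call=frozenset([rec["j"]]),
            duplicate_count=rec["count"],
            productive=rec["productive"],
        )
        for nt, rec in sorted(table.items())
        if rec["count"] > 0
    ]
    sample = RepertoireSample(
        sample_id=sample_id,
        clonotypes=clonotypes,
        fish_id=fish_id,
        chain=chain,
        replicate=replicate,
        total_mapped_reads=clone_model.total_reads,
    )
    truth = pd.DataFrame(
        {
            "v_id": [c.v_id for c in clones],
            "d_id": [c.d_id for c in clones],
            "j_id": [c.j_id for c in clones],
            "cdr3_nt": [c.cdr3_nt for c in clones],
            "cdr3_aa": [c.cdr3_aa for c in clones],
            "productive": [c.productive for c in clones],
            "duplicate_count": counts,
            "v_trim": [c.trims.get("v_3", 0) for c in clones],
            "j_trim": [c.trims.get("j_5", 0) for c in clones],
            "insertions": ["|".join(f"{k}:{v}" for k, v in c.insertions.items()) for c in clones],
        }
    )
    return sample, truth
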