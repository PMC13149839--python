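"""Neighbour-joining phylogenies with bootstrap support.

Distances are p-distance (mismatch fraction) or Kimura 2-parameter,
optionally with gamma-distributed rate variation; ambiguous sites and
gaps are removed pairwise.  The tree search is the classic iterative
Q-matrix neighbour joining with deterministic lexicographic tie-breaks;
negative branch lengths are clamped to zero with the deficit moved to
the sister branch.  Bootstrap resamples alignment columns with
replacement and reports the percentage of replicates containing each
internal bipartition.
"""

from __future__ import annotations

import math

import numpy as np
from skbio import TreeNode

_NT = set(b"ACGTU")
_PURINES = set(b"AG")

MODELS = ("p-distance", "k2p", "k2p-gamma")


def _to_matrix(alignment: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    names = [n for n, _ in alignment]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    lengths = {len(s) for _, s in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment columns must be equal length")
    arr = np.array(
        [np.frombuffer(s.upper().encode(), dtype=np.uint8) for _, s in alignment]
    )
    return names, arr


def _usable_mask(row_a: np.ndarray, row_b: np.ndarray, is_nt: bool) -> np.ndarray:
    if is_nt:
        ok = np.isin(row_a, list(_NT)) & np.isin(row_b, list(_NT))
    else:
        bad = np.frombuffer(b"-.X*?", dtype=np.uint8)
        ok = ~np.isin(row_a, bad) & ~np.isin(row_b, bad)
    return ok


def _looks_like_nt(arr: np.ndarray) -> bool:
    letters = set(arr.tobytes())
    return letters <= (set(b"ACGTUN-.?") | set(b" "))


def p_distance_matrix(alignment: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Pairwise mismatch fractions with pairwise deletion of gap and
    ambiguous columns."""
    names, arr = _to_matrix(alignment)
    is_nt = _looks_like_nt(arr)
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = _usable_mask(arr[i], arr[j], is_nt)
            usable = int(ok.sum())
            if usable == 0:
                raise ValueError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            mism = int((arr[i][ok] != arr[j][ok]).sum())
            dist[i, j] = dist[j, i] = mism / usable
    return names, dist


def k2p_distance_matrix(
    alignment: list[tuple[str, str]], gamma_shape: float | None = None
) -> tuple[list[str], np.ndarray]:
    """Kimura 2-parameter distances (nucleotides only), pairwise deletion.

    With ``gamma_shape`` a, the Jin-Nei gamma-rate correction
    d = a/2 [(1-2P-Q)^(-1/a) - 1] + a/4 [(1-2Q)^(-1/a) - 1] is used.
    """
    names, arr = _to_matrix(alignment)
    if not _looks_like_nt(arr):
        raise ValueError("K2P distances require a nucleotide alignment")
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = _usable_mask(arr[i], arr[j], True)
            usable = int(ok.sum())
            if usable == 0:
                raise ValueError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            a, b = arr[i][ok], arr[j][ok]
            diff = a != b
            pur_a = np.isin(a, list(_PURINES))
            pur_b = np.isin(b, list(_PURINES))
            transitions = int((diff & (pur_a == pur_b)).sum())
            transversions = int((diff & (pur_a != pur_b)).sum())
            P, Q = transitions / usable, transversions / usable
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                raise ValueError(
                    f"K2P distance undefined (saturated) between "
                    f"{names[i]} and {names[j]}"
                )
            if gamma_shape is None:
                d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            else:
                g = gamma_shape
                d = (g / 2) * (w1 ** (-1 / g) - 1) + (g / 4) * (w2 ** (-1 / g) - 1)
            dist[i, j] = dist[j, i] = d
    return names, dist


def distance_matrix(
    alignment: list[tuple[str, str]],
    model: str = "p-distance",
    gamma_shape: float = 5.0,
) -> tuple[list[str], np.ndarray]:
    if model == "p-distance":
        return p_distance_matrix(alignment)
    if model == "k2p":
        return k2p_distance_matrix(alignment)
    if model == "k2p-gamma":
        return k2p_distance_matrix(alignment, gamma_shape=gamma_shape)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def neighbor_joining(names: list[str], dist: np.ndarray) -> TreeNode:
    """Classic neighbour joining on a distance matrix.

    Ties in the Q matrix break on the lexicographically smallest taxon
    pair (internal nodes are represented by their smallest leaf name),
    so the result is deterministic.  NJ is exact on additive matrices.
    """
    n = len(names)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [TreeNode(name=name) for name in names]
    reps = list(names)  # lexicographic representative per active node
    D = dist.astype(float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                key = (q, tuple(sorted((reps[idx[a]], reps[idx[b]]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = idx[a], idx[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lj = sub[a, b] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_index = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        new_row = np.zeros(new_index + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[new_index, k] = D[k, new_index] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_index]
        del new_row
    i, j = active
    root = TreeNode()
    d = float(D[i, j])
    nodes[i].length = d / 2
    nodes[j].length = d / 2
    root.append(nodes[i])
    root.append(nodes[j])
    return root


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalised to the side not containing
    the lexicographically first taxon."""
    anchor = min(taxa)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            parts.add(side)
    return parts


def nj_tree(
    alignment: list[tuple[str, str]],
    model: str = "p-distance",
    gamma_shape: float = 5.0,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> TreeNode:
    """Build an NJ tree from an alignment, optionally with bootstrap.

    Bootstrap resamples columns with replacement (``n_bootstrap``
    replicates, deterministic under ``seed``); internal nodes get a
    ``bootstrap_support`` attribute in [0, 100] and carry the rounded
    value as their name so it appears as a label in newick output.
    """
    if len(alignment) < 3:
        raise ValueError("need at least three taxa")
    names, dist = distance_matrix(alignment, model, gamma_shape)
    tree = neighbor_joining(names, dist)
    if n_bootstrap > 0:
        taxa = frozenset(names)
        ref_parts = _bipartitions(tree, taxa)
        counts = {p: 0 for p in ref_parts}
        rng = np.random.default_rng(seed)
        length = len(alignment[0][1])
        seqs = [s for _, s in alignment]
        for _ in range(n_bootstrap):
            cols = rng.integers(0, length, size=length)
            resampled = [
                (name, "".join(seq[c] for c in cols))
                for name, seq in zip(names, seqs)
            ]
            try:
                bnames, bdist = distance_matrix(resampled, model, gamma_shape)
            except ValueError:
                continue  # saturated replicate contributes no support
            btree = neighbor_joining(bnames, bdist)
            for p in _bipartitions(btree, taxa):
                if p in counts:
                    counts[p] += 1
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if min(taxa) in side:
                side = taxa - side
            if side in counts:
                support = 100.0 * counts[side] / n_bootstrap
                node.bootstrap_support = support
                node.name = str(int(round(support)))
    return tree
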