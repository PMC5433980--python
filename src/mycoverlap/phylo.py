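"""Faith phylogenetic diversity and exact extremal PD over equal-size leaf sets.

PD convention
-------------
``faith_pd`` sums the branch lengths of the minimal subtree spanning the
leaf set, *excluding* the stem edge above the set's most recent common
ancestor; a singleton set has PD 0. This is the unrooted (minimal spanning
subtree) form of Faith's PD: an edge contributes iff it separates members
of the set from each other, i.e. its clade contains at least one but not
all of the selected leaves.

Under this convention the greedy leaf-addition algorithm started from the
most distant leaf pair is provably optimal for the maximum-PD subset of
every size (its solutions are nested), and a knapsack-style dynamic
programme over the tree yields the exact minimum-PD subset in
O(n_nodes * k^2).

Scaled PD normalises an observed host set's PD within the exact range
attainable by *any* equal-size subset of the fungal pool:
``PD' = (PD - PDmin) / (PDmax - PDmin)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .tree import PhyloTree

__all__ = [
    "PDStats",
    "faith_pd",
    "faith_pd_batch",
    "max_pd_subset",
    "max_pd_chain",
    "min_pd_subset",
    "min_pd_values",
    "pd_extremes",
    "sample_pd_range",
    "scaled_pd",
]


@dataclass(frozen=True)
class PDStats:
    """PD of one host set with its size-k extremes and min-max scaled value.

    ``scaled_pd`` is None (undefined) when every k-subset has the same PD,
    i.e. pd_max == pd_min.
    """

    pd: float
    pd_min: float
    pd_max: float
    scaled_pd: float | None
    k: int


# ---------------------------------------------------------------------- #
# Faith PD
# ---------------------------------------------------------------------- #


def faith_pd(tree: PhyloTree, leaves: Iterable[str]) -> float:
    """Branch-length sum of the minimal subtree spanning ``leaves``.

    Singleton sets return 0; the stem above the set's MRCA is excluded.
    """
    labels = list(leaves)
    if not labels:
        raise DomainError("leaf set must be non-empty")
    cols = tree.leaf_ids(labels)
    if len(set(labels)) != len(labels):
        cols = np.unique(cols)
    k = len(cols)
    counts = tree.leaf_matrix[:, cols].sum(axis=1)
    mask = (counts >= 1) & (counts < k)
    return float(tree.branch_length[mask].sum())


def faith_pd_batch(tree: PhyloTree, membership: np.ndarray) -> np.ndarray:
    """PD of many leaf sets at once.

    ``membership`` is boolean (n_sets, n_leaves) in :attr:`PhyloTree.leaf_labels`
    column order. Rows with a single leaf get 0.
    """
    U = np.asarray(membership, dtype=np.float64)
    sizes = U.sum(axis=1)
    if (sizes < 1).any():
        raise DomainError("every leaf set must be non-empty")
    counts = U @ tree.leaf_matrix.T.astype(np.float64)
    mask = (counts >= 0.5) & (counts < sizes[:, None] - 0.5)
    return mask @ tree.branch_length


# ---------------------------------------------------------------------- #
# maximum PD: greedy leaf addition
# ---------------------------------------------------------------------- #


def _check_k(tree: PhyloTree, k: int) -> None:
    if not 1 <= k <= tree.n_leaves:
        raise DomainError(f"k={k} out of range [1, {tree.n_leaves}]")


def max_pd_chain(tree: PhyloTree, k_max: int) -> tuple[list[str], np.ndarray]:
    """Greedy chain of leaves whose prefixes maximise PD for every size.

    Returns the pick order (length k_max) and the array ``pd[k]`` for
    k = 0..k_max (pd[0] unused, pd[1] = 0). The chain starts from the most
    distant leaf pair; ties are broken toward lexicographically smaller
    labels so the result is deterministic.
    """
    _check_k(tree, k_max)
    labels = tree.leaf_labels
    if k_max == 1:
        return [labels[0]], np.array([0.0, 0.0])

    D = tree.patristic_matrix
    iu, ju = np.triu_indices(tree.n_leaves, 1)
    t = int(np.argmax(D[iu, ju]))  # first max = lexicographically smallest pair
    i, j = int(iu[t]), int(ju[t])
    picked = [i, j]
    pd_values = [0.0, 0.0, float(D[i, j])]

    M = tree.leaf_matrix
    bl = tree.branch_length
    counts = M[:, i].astype(np.int64) + M[:, j]
    in_set = np.zeros(tree.n_leaves, dtype=bool)
    in_set[[i, j]] = True

    for m in range(2, k_max):
        cand = np.flatnonzero(~in_set)
        X = counts[:, None] + M[:, cand]
        mask = (X >= 1) & (X < m + 1)
        pds = bl @ mask
        t = int(np.argmax(pds))  # argmax keeps the first (lexico-smallest)
        b = int(cand[t])
        picked.append(b)
        pd_values.append(float(pds[t]))
        counts += M[:, b]
        in_set[b] = True

    return [labels[p] for p in picked], np.asarray(pd_values)


def max_pd_subset(tree: PhyloTree, k: int) -> tuple[set[str], float]:
    """Exact maximum-PD k-leaf subset (greedy, provably optimal) and its PD."""
    chain, values = max_pd_chain(tree, k)
    return set(chain[:k]), float(values[k])


# ---------------------------------------------------------------------- #
# minimum PD: dynamic programme over the tree
# ---------------------------------------------------------------------- #


def _min_pd_dp(tree: PhyloTree, k_max: int):
    """Per-node tables f[v][j] = min cost of connecting j clade leaves to v."""
    INF = math.inf
    n = tree.n_nodes
    bl = tree.branch_length
    children = tree.children
    f: list[list[float]] = [[] for _ in range(n)]
    layers: list[list[tuple[list[float], list[float]]] | None] = [None] * n

    for v in range(n):  # postorder
        if not children[v]:
            f[v] = [0.0, 0.0]
            continue
        acc = [0.0]
        lay = []
        for c in children[v]:
            fc = f[c]
            g = [0.0] + [fc[j] + bl[c] for j in range(1, len(fc))]
            lay.append((acc, g))
            top = min(k_max, len(acc) - 1 + len(g) - 1)
            new = [INF] * (top + 1)
            for a, va in enumerate(acc):
                if va == INF:
                    continue
                bmax = min(len(g) - 1, top - a)
                for b in range(bmax + 1):
                    s = va + g[b]
                    if s < new[a + b]:
                        new[a + b] = s
            acc = new
        f[v] = acc
        layers[v] = lay
    return f, layers


def min_pd_values(tree: PhyloTree, k_max: int) -> np.ndarray:
    """Exact minimum PD over all k-subsets, for every k = 1..k_max."""
    _check_k(tree, k_max)
    f, _ = _min_pd_dp(tree, k_max)
    out = np.full(k_max + 1, np.inf)
    out[0] = 0.0
    for table in f:
        for j in range(1, min(len(table), k_max + 1)):
            if table[j] < out[j]:
                out[j] = table[j]
    return out


def min_pd_subset(tree: PhyloTree, k: int) -> tuple[set[str], float]:
    """Exact minimum-PD k-leaf subset and its PD (DP with backtracking)."""
    _check_k(tree, k)
    f, layers = _min_pd_dp(tree, k)
    best_v, best = -1, math.inf
    for v in range(tree.n_nodes):
        if len(f[v]) > k and f[v][k] < best:
            best_v, best = v, f[v][k]

    label_of = {i: lab for lab, i in tree.leaf_index.items()}
    leaves: list[str] = []

    def backtrack(v: int, j: int) -> None:
        if not tree.children[v]:
            if j == 1:
                leaves.append(label_of[v])
            return
        lay = layers[v]
        remaining = j
        # walk children in reverse, splitting `remaining` between the child
        # and the prefix table that preceded it
        for ci in range(len(lay) - 1, -1, -1):
            acc, g = lay[ci]
            choice, cbest = 0, math.inf
            for b in range(min(len(g) - 1, remaining) + 1):
                a = remaining - b
                if a < len(acc):
                    s = acc[a] + g[b]
                    if s < cbest:
                        choice, cbest = b, s
            if choice >= 1:
                backtrack(tree.children[v][ci], choice)
            remaining -= choice
        assert remaining == 0

    backtrack(best_v, k)
    return set(leaves), float(best)


def pd_extremes(tree: PhyloTree, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """(pd_min[k], pd_max[k]) arrays for every k = 1..k_max, computed exactly."""
    _, max_vals = max_pd_chain(tree, k_max)
    min_vals = min_pd_values(tree, k_max)
    return min_vals, max_vals


# ---------------------------------------------------------------------- #
# Monte-Carlo range and scaling
# ---------------------------------------------------------------------- #


def sample_pd_range(
    tree: PhyloTree, k: int, n_samples: int, seed: int
) -> tuple[float, float]:
    """(min, max) PD over ``n_samples`` uniform k-subsets; seed-reproducible."""
    _check_k(tree, k)
    if n_samples < 1:
        raise DomainError("n_samples must be >= 1")
    if k == 1:
        return (0.0, 0.0)
    rng = np.random.default_rng(seed)
    n = tree.n_leaves
    pds = np.empty(n_samples)
    chunk = max(1, min(n_samples, 4096))
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :k]
        U = np.zeros((m, n), dtype=bool)
        np.put_along_axis(U, idx, True, axis=1)
        pds[done : done + m] = faith_pd_batch(tree, U)
        done += m
    return (float(pds.min()), float(pds.max()))


def scaled_pd(tree: PhyloTree, leaves: Iterable[str]) -> PDStats:
    """PD of a host set scaled within the exact range of its size class."""
    labels = sorted(set(leaves))
    k = len(labels)
    pd = faith_pd(tree, labels)
    if k == tree.n_leaves:
        return PDStats(pd=pd, pd_min=pd, pd_max=pd, scaled_pd=None, k=k)
    lo = float(min_pd_values(tree, k)[k])
    _, hi_vals = max_pd_chain(tree, k)
    hi = float(hi_vals[k])
    scaled = None if hi <= lo else (pd - lo) / (hi - lo)
    return PDStats(pd=pd, pd_min=lo, pd_max=hi, scaled_pd=scaled, k=k)
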