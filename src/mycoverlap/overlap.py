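"""Pairwise and group-level host-sharing statistics.

For plants i, j with host counts d_i, d_j and shared-host count
C_ij = |hosts(i) & hosts(j)|:

* count dissimilarity  |d_i - d_j|
* Bray-Curtis (presence form)  1 - 2 C_ij / (d_i + d_j)
* min-overlap  C_ij / min(d_i, d_j)  -- sharing relative to the maximum
  sharing possible for the pair.

Group overlap is the mean of min-overlap over all unordered member pairs.
The raw statistic is sometimes written as the plain sum over pairs; within
a fixed group size the two differ by the constant factor C(n,2), so min-max
scaling inside a same-size ensemble is identical either way. The mean is
used here because it stays on [0, 1] across sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .errors import DomainError
from .io import HostIncidence
from .phylo import faith_pd
from .tree import PhyloTree

__all__ = [
    "PairwiseMatrix",
    "shared_hosts",
    "count_dissimilarity",
    "bray_curtis",
    "min_overlap",
    "pairwise_matrix",
    "group_overlap",
    "group_overlap_sum",
    "combined_pd",
]

MEASURES = ("count-dissimilarity", "bray-curtis", "min-overlap")


@dataclass
class PairwiseMatrix:
    """Symmetric plant x plant matrix of one pairwise measure."""

    plant_ids: list[str]
    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.plant_ids)
        if self.values.shape != (n, n):
            raise DomainError("matrix shape does not match plant ids")
        if not np.allclose(self.values, self.values.T):
            raise DomainError("pairwise matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.plant_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]


def _pair_counts(inc: HostIncidence, i: str, j: str) -> tuple[int, int, int]:
    if i == j:
        raise DomainError("pairwise measures need two distinct plants")
    ri, rj = inc.matrix[inc.row(i)], inc.matrix[inc.row(j)]
    return int(ri.sum()), int(rj.sum()), int((ri & rj).sum())


def shared_hosts(inc: HostIncidence, i: str, j: str) -> int:
    """C_ij: number of fungal OTUs hosted by both plants."""
    return _pair_counts(inc, i, j)[2]


def count_dissimilarity(inc: HostIncidence, i: str, j: str) -> int:
    """|d_i - d_j|: difference in host-set size."""
    di, dj, _ = _pair_counts(inc, i, j)
    return abs(di - dj)


def bray_curtis(inc: HostIncidence, i: str, j: str) -> float:
    """1 - 2 C_ij / (d_i + d_j), in [0, 1]; 0 iff identical host sets."""
    di, dj, c = _pair_counts(inc, i, j)
    return 1.0 - 2.0 * c / (di + dj)


def min_overlap(inc: HostIncidence, i: str, j: str) -> float:
    """C_ij / min(d_i, d_j), in [0, 1]; 1 iff one host set nests in the other."""
    di, dj, c = _pair_counts(inc, i, j)
    return c / min(di, dj)


def pairwise_matrix(inc: HostIncidence, measure: str) -> PairwiseMatrix:
    """Full symmetric matrix of one measure over all plants.

    ``min-overlap`` is a similarity (1 on the diagonal conceptually, stored
    as 0 there so dissimilarity callers can use ``1 - values`` directly);
    the other two are dissimilarities with a zero diagonal.
    """
    if measure not in MEASURES:
        raise DomainError(f"unknown measure {measure!r}; pick one of {MEASURES}")
    if len(inc.plant_ids) < 2:
        raise DomainError("need at least two plants")
    X = inc.matrix.astype(np.float64)
    d = X.sum(axis=1)
    C = X @ X.T
    if measure == "count-dissimilarity":
        vals = np.abs(d[:, None] - d[None, :])
    elif measure == "bray-curtis":
        vals = 1.0 - 2.0 * C / (d[:, None] + d[None, :])
    else:
        vals = C / np.minimum(d[:, None], d[None, :])
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(list(inc.plant_ids), vals, measure)


def group_overlap(inc: HostIncidence, group: Iterable[str]) -> float:
    """Mean min-overlap over all unordered pairs in the group, in [0, 1]."""
    members = sorted(set(group))
    if len(members) < 2:
        raise DomainError("group overlap needs at least two plants")
    vals = [min_overlap(inc, a, b) for a, b in combinations(members, 2)]
    return float(np.mean(vals))


def group_overlap_sum(inc: HostIncidence, group: Iterable[str]) -> float:
    """Plain sum over pairs; equals group_overlap * C(n, 2)."""
    members = sorted(set(group))
    if len(members) < 2:
        raise DomainError("group overlap needs at least two plants")
    return float(
        sum(min_overlap(inc, a, b) for a, b in combinations(members, 2))
    )


def combined_pd(tree: PhyloTree, inc: HostIncidence, group: Iterable[str]) -> float:
    """Faith PD of the union of the members' host sets."""
    members = list(group)
    if not members:
        raise DomainError("group must be non-empty")
    return faith_pd(tree, inc.union_hosts(members))
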