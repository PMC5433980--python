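"""Exhaustive same-size group ensembles and within-ensemble min-max scaling.

An *ensemble* of size n is the set of all C(|pool|, n) groups of n plant
species from the species pool. Each group carries its combined fungal-host
PD (PD of the union host set) and its host overlap (mean pairwise
min-overlap). Scaled metrics are min-max normalised against the range the
full same-size ensemble generates, so a value of 1 means "the most
diverse / most overlapping group of this size that the pool allows".
Observed field communities are scaled against the generated ensemble of
their own size.

A group is classified *same-location* when at least one locality's sampled
species set contains every member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, LookupError_
from .io import HostIncidence, PlantMetadata
from .overlap import pairwise_matrix
from .phylo import faith_pd_batch
from .tree import PhyloTree

__all__ = [
    "GroupRecord",
    "Ensemble",
    "enumerate_groups",
    "evaluate_groups",
    "scale_within_ensemble",
    "scale_against",
    "classify_location",
    "group_covariates",
    "herfindahl_index",
]


@dataclass
class GroupRecord:
    """One plant group with its diversity/overlap metrics and covariates."""

    members: tuple[str, ...]
    provenance: str = "generated"  # generated | observed
    combined_pd: float | None = None
    overlap: float | None = None
    scaled_pd: float | None = None
    scaled_overlap: float | None = None
    same_location: bool | None = None
    total_specimens: int | None = None
    total_otus: int | None = None
    herfindahl: float | None = None

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class Ensemble:
    """All same-size groups over a species pool, with their raw metric ranges."""

    n: int
    pool: tuple[str, ...]
    records: list[GroupRecord] = field(default_factory=list)
    pd_range: tuple[float, float] | None = None
    overlap_range: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "members": ";".join(r.members),
                    "n": r.n,
                    "provenance": r.provenance,
                    "combined_pd": r.combined_pd,
                    "overlap": r.overlap,
                    "scaled_pd": r.scaled_pd,
                    "scaled_overlap": r.scaled_overlap,
                    "same_location": r.same_location,
                    "total_specimens": r.total_specimens,
                    "total_otus": r.total_otus,
                    "herfindahl": r.herfindahl,
                }
            )
        return pd.DataFrame(rows)


def enumerate_groups(plant_ids: Sequence[str], n: int) -> Ensemble:
    """All C(|pool|, n) groups in deterministic lexicographic order."""
    pool = tuple(sorted(set(plant_ids)))
    if not 2 <= n <= len(pool):
        raise DomainError(f"group size {n} out of range [2, {len(pool)}]")
    records = [
        GroupRecord(members=g, provenance="generated")
        for g in combinations(pool, n)
    ]
    ens = Ensemble(n=n, pool=pool, records=records)
    assert len(ens) == comb(len(pool), n)
    return ens


# ---------------------------------------------------------------------- #
# metric evaluation (vectorised over all groups at once)
# ---------------------------------------------------------------------- #


def _membership(records: Iterable[GroupRecord], inc: HostIncidence) -> np.ndarray:
    rows = {p: i for i, p in enumerate(inc.plant_ids)}
    recs = list(records)
    G = np.zeros((len(recs), len(inc.plant_ids)), dtype=bool)
    for g, r in enumerate(recs):
        for p in r.members:
            if p not in rows:
                raise LookupError_(f"unknown plant id in group: {p!r}")
            G[g, rows[p]] = True
    return G


def evaluate_groups(
    records: list[GroupRecord],
    tree: PhyloTree,
    inc: HostIncidence,
    meta: PlantMetadata | None = None,
) -> list[GroupRecord]:
    """Fill combined_pd, overlap, covariates and the location flag in place."""
    if not records:
        return records
    G = _membership(records, inc)

    # union host sets and combined PD
    union = (G.astype(np.int8) @ inc.matrix) > 0  # groups x fungi
    cols = tree.leaf_ids(inc.fungus_ids)
    U = np.zeros((len(records), tree.n_leaves), dtype=bool)
    U[:, cols] = union
    pds = faith_pd_batch(tree, U)
    n_otus = union.sum(axis=1)

    # mean pairwise min-overlap
    O = pairwise_matrix(inc, "min-overlap").values
    sizes = G.sum(axis=1)
    pair_counts = sizes * (sizes - 1) / 2
    Gf = G.astype(np.float64)
    sums = ((Gf @ O) * Gf).sum(axis=1) / 2.0
    with np.errstate(invalid="ignore"):
        overlaps = np.where(pair_counts > 0, sums / pair_counts, np.nan)

    for r, pdv, ov, no in zip(records, pds, overlaps, n_otus):
        r.combined_pd = float(pdv)
        r.overlap = float(ov)
        r.total_otus = int(no)

    if meta is not None:
        spec = np.array([meta.specimens_of(p) for p in inc.plant_ids], dtype=float)
        totals = Gf @ spec
        herf = ((Gf * spec) ** 2).sum(axis=1) / totals**2
        L = np.zeros((len(meta.localities), len(inc.plant_ids)), dtype=bool)
        for li, loc in enumerate(meta.localities):
            for p in meta.species_at(loc):
                if p in inc.plant_ids:
                    L[li, inc.plant_ids.index(p)] = True
        missing = Gf @ (~L).T.astype(np.float64)  # members outside each locality
        same = (missing == 0).any(axis=1)
        for r, tot, h, s in zip(records, totals, herf, same):
            r.total_specimens = int(tot)
            r.herfindahl = float(h)
            r.same_location = bool(s)
    return records


# ---------------------------------------------------------------------- #
# scaling
# ---------------------------------------------------------------------- #


def _minmax(values: Iterable[float]) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    return float(arr.min()), float(arr.max())


def scale_within_ensemble(ens: Ensemble) -> Ensemble:
    """Min-max scale each record's metrics against the ensemble's own range."""
    if any(r.combined_pd is None or r.overlap is None for r in ens.records):
        raise DomainError("evaluate_groups must run before scaling")
    ens.pd_range = _minmax(r.combined_pd for r in ens.records)
    ens.overlap_range = _minmax(r.overlap for r in ens.records)
    for r in ens.records:
        r.scaled_pd = _scale(r.combined_pd, ens.pd_range)
        r.scaled_overlap = _scale(r.overlap, ens.overlap_range)
    return ens


def scale_against(records: list[GroupRecord], ens: Ensemble) -> list[GroupRecord]:
    """Scale observed groups against a generated same-size ensemble's range."""
    if ens.pd_range is None or ens.overlap_range is None:
        raise DomainError("ensemble must be scaled first")
    for r in records:
        if r.n != ens.n:
            raise DomainError(f"group size {r.n} does not match ensemble size {ens.n}")
        r.scaled_pd = _scale(r.combined_pd, ens.pd_range)
        r.scaled_overlap = _scale(r.overlap, ens.overlap_range)
    return records


def _scale(value: float, rng: tuple[float, float]) -> float | None:
    lo, hi = rng
    if hi <= lo:  # degenerate range: scaled value undefined
        return None
    return (value - lo) / (hi - lo)


# ---------------------------------------------------------------------- #
# location and covariates (scalar forms)
# ---------------------------------------------------------------------- #


def classify_location(group: Iterable[str], meta: PlantMetadata) -> bool:
    """True iff some single locality's species set contains every member."""
    members = list(group)
    loc_sets = [meta.localities_of(p) for p in members]
    common = frozenset.intersection(*loc_sets)
    return len(common) > 0


def herfindahl_index(counts: Sequence[float]) -> float:
    """Sum of squared proportional shares; 1/len(counts) when equal, 1 for one."""
    arr = np.asarray(counts, dtype=float)
    if arr.sum() <= 0:
        raise DomainError("specimen counts must be positive")
    p = arr / arr.sum()
    return float((p**2).sum())


def group_covariates(
    group: Iterable[str], inc: HostIncidence, meta: PlantMetadata
) -> tuple[int, int, float]:
    """(total specimens, distinct OTUs in the union host set, Herfindahl index)."""
    members = sorted(set(group))
    spec = [meta.specimens_of(p) for p in members]
    total_otus = len(inc.union_hosts(members))
    return int(sum(spec)), total_otus, herfindahl_index(spec)
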