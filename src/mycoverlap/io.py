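"""Readers, writers and cross-validation for the pipeline's file formats.

Formats
-------
* fungal (or plant) phylogeny: Newick with mandatory branch lengths;
* incidence: wide TSV, first column the plant id, remaining columns one
  fungal OTU each, cells 0/1 (presence of the OTU in >=1 specimen of the
  species);
* long table: one row per (specimen, species, locality, OTU) detection,
  collapsed on read to the binary species x OTU matrix plus metadata;
* metadata: TSV with columns species, family, locality, n_specimens
  (one row per sampled population, i.e. per species-locality pair);
* communities: TSV with columns community_id, species (one row per member).

All TSVs are UTF-8, tab-delimited, header required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import LookupError_, MalformedInputError, ValidationError
from .tree import PhyloTree

__all__ = [
    "HostIncidence",
    "PlantMetadata",
    "CommunitySet",
    "read_newick",
    "write_newick",
    "read_incidence",
    "write_incidence",
    "read_long_table",
    "read_metadata",
    "write_metadata",
    "read_communities",
    "write_communities",
    "cross_validate",
]


# ---------------------------------------------------------------------- #
# domain types
# ---------------------------------------------------------------------- #


class HostIncidence:
    """Binary plant x fungus presence matrix.

    Row sums are the host counts ``d_i``; column labels are fungal OTU ids
    that must resolve as leaves of the fungal phylogeny when the two are
    used together.
    """

    def __init__(self, plant_ids: Iterable[str], fungus_ids: Iterable[str], matrix) -> None:
        self.plant_ids = list(plant_ids)
        self.fungus_ids = list(fungus_ids)
        self.matrix = np.asarray(matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.plant_ids), len(self.fungus_ids)):
            raise ValidationError("incidence matrix shape does not match id lists")
        if len(set(self.plant_ids)) != len(self.plant_ids):
            raise ValidationError("duplicate plant id in incidence table")
        if len(set(self.fungus_ids)) != len(self.fungus_ids):
            raise ValidationError("duplicate fungus id in incidence table")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("incidence cells must be 0 or 1")
        if (self.matrix.sum(axis=1) < 1).any():
            bad = [p for p, s in zip(self.plant_ids, self.matrix.sum(axis=1)) if s < 1]
            raise ValidationError(f"plants with empty host set: {bad}")
        self._row = {p: i for i, p in enumerate(self.plant_ids)}

    @property
    def d(self) -> np.ndarray:
        """Host counts d_i, one per plant (row sums)."""
        return self.matrix.sum(axis=1).astype(np.int64)

    def row(self, plant_id: str) -> int:
        try:
            return self._row[plant_id]
        except KeyError:
            raise LookupError_(f"unknown plant id: {plant_id!r}") from None

    def host_set(self, plant_id: str) -> frozenset[str]:
        r = self.matrix[self.row(plant_id)]
        return frozenset(f for f, v in zip(self.fungus_ids, r) if v)

    def union_hosts(self, plant_ids: Iterable[str]) -> frozenset[str]:
        rows = [self.row(p) for p in plant_ids]
        mask = self.matrix[rows].any(axis=0)
        return frozenset(f for f, v in zip(self.fungus_ids, mask) if v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.plant_ids, columns=self.fungus_ids)


class PlantMetadata:
    """Per-population sampling records: species, family, locality, specimen count."""

    REQUIRED = ("species", "family", "locality", "n_specimens")

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        t = table.loc[:, list(self.REQUIRED)].copy()
        t["n_specimens"] = t["n_specimens"].astype(int)
        if (t["n_specimens"] < 1).any():
            raise ValidationError("population with fewer than one specimen")
        if t.duplicated(["species", "locality"]).any():
            raise ValidationError("duplicate species-locality population row")
        fam = t.groupby("species")["family"].nunique()
        if (fam > 1).any():
            raise ValidationError("species assigned to more than one family")
        self.table = t.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    @property
    def localities(self) -> list[str]:
        return sorted(self.table["locality"].unique())

    def localities_of(self, species: str) -> frozenset[str]:
        sub = self.table.loc[self.table["species"] == species, "locality"]
        if sub.empty:
            raise LookupError_(f"species not in metadata: {species!r}")
        return frozenset(sub)

    def species_at(self, locality: str) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["locality"] == locality, "species"])

    def specimens_of(self, species: str) -> int:
        sub = self.table.loc[self.table["species"] == species, "n_specimens"]
        if sub.empty:
            raise LookupError_(f"species not in metadata: {species!r}")
        return int(sub.sum())

    def multi_species_localities(self) -> list[str]:
        counts = self.table.groupby("locality")["species"].nunique()
        return sorted(counts.index[counts >= 2])


@dataclass
class CommunitySet:
    """Named groups of co-occurring plant species."""

    members: dict[str, list[str]]
    provenance: str = "observed"  # observed | generated

    def __post_init__(self) -> None:
        for cid, plants in self.members.items():
            if len(plants) < 2:
                raise ValidationError(f"community {cid!r} has fewer than two members")
            if len(set(plants)) != len(plants):
                raise ValidationError(f"community {cid!r} lists a member twice")

    def __iter__(self):
        return iter(sorted(self.members.items()))

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------- #
# readers / writers
# ---------------------------------------------------------------------- #


def read_newick(path) -> PhyloTree:
    """Parse a Newick tree file; branch lengths are mandatory on non-root edges."""
    text = Path(path).read_text(encoding="utf-8")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise MalformedInputError(f"could not read TSV {path}: {exc}") from exc


def read_incidence(path) -> HostIncidence:
    """Read the wide plant x OTU 0/1 table (first column = plant id)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise MalformedInputError("incidence table needs a plant-id column plus OTU columns")
    plants = df.iloc[:, 0].tolist()
    fungi = df.columns[1:].tolist()
    cells = df.iloc[:, 1:]
    if not cells.isin(["0", "1"]).all().all():
        raise ValidationError("incidence cells must be 0 or 1")
    return HostIncidence(plants, fungi, cells.astype(np.int8).to_numpy())


def write_incidence(inc: HostIncidence, path) -> None:
    df = inc.to_frame()
    df.index.name = "species"
    df.to_csv(path, sep="\t")


def read_long_table(path) -> tuple[HostIncidence, PlantMetadata]:
    """Collapse a long (specimen, species, family, locality, otu) table.

    Incidence is binary at species level (an OTU counts as a host of the
    species if it was detected in at least one specimen); the specimen and
    locality columns populate the metadata.
    """
    df = _read_tsv(path)
    required = {"specimen", "species", "family", "locality", "otu"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(f"long table missing columns: {sorted(missing)}")
    wide = pd.crosstab(df["species"], df["otu"]).clip(upper=1)
    inc = HostIncidence(wide.index.tolist(), wide.columns.tolist(), wide.to_numpy())
    pops = (
        df.groupby(["species", "family", "locality"])["specimen"]
        .nunique()
        .rename("n_specimens")
        .reset_index()
    )
    return inc, PlantMetadata(pops)


def read_metadata(path) -> PlantMetadata:
    df = _read_tsv(path)
    return PlantMetadata(df)


def write_metadata(meta: PlantMetadata, path) -> None:
    meta.table.sort_values(["species", "locality"]).to_csv(path, sep="\t", index=False)


def read_communities(path, provenance: str = "observed") -> CommunitySet:
    df = _read_tsv(path)
    if not {"community_id", "species"} <= set(df.columns):
        raise MalformedInputError("communities table needs community_id and species columns")
    members = {
        cid: sub["species"].tolist() for cid, sub in df.groupby("community_id", sort=True)
    }
    return CommunitySet(members, provenance=provenance)


def write_communities(comm: CommunitySet, path) -> None:
    rows = [
        {"community_id": cid, "species": sp}
        for cid, plants in comm
        for sp in plants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- #
# cross-validation
# ---------------------------------------------------------------------- #


@dataclass
class ValidationReport:
    """Cross-reference check between the four inputs (report-only)."""

    fungi_not_in_tree: list[str] = field(default_factory=list)
    species_not_in_metadata: list[str] = field(default_factory=list)
    community_members_not_in_incidence: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.fungi_not_in_tree
            or self.species_not_in_metadata
            or self.community_members_not_in_incidence
        )

    def entries(self) -> list[str]:
        out = [f"fungus not a tree leaf: {f}" for f in self.fungi_not_in_tree]
        out += [f"species missing from metadata: {s}" for s in self.species_not_in_metadata]
        out += [
            f"community member missing from incidence: {s}"
            for s in self.community_members_not_in_incidence
        ]
        return out


def cross_validate(
    tree: PhyloTree,
    inc: HostIncidence,
    meta: PlantMetadata | None = None,
    comm: CommunitySet | None = None,
) -> ValidationReport:
    """List dangling cross-references; an empty report means admissible data."""
    report = ValidationReport()
    leaves = set(tree.leaf_labels)
    report.fungi_not_in_tree = sorted(set(inc.fungus_ids) - leaves)
    if meta is not None:
        known = set(meta.species)
        report.species_not_in_metadata = sorted(set(inc.plant_ids) - known)
    if comm is not None:
        plants = set(inc.plant_ids)
        missing = {s for _, mem in comm for s in mem if s not in plants}
        report.community_members_not_in_incidence = sorted(missing)
    return report
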