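"""Synthetic plant-fungus datasets with location-structured host sharing.

The generator emulates the statistical shape of a tropical
mycoheterotroph survey: a pool of fungal OTUs on an ultrametric
phylogeny, a set of plant species whose host counts span a heavy-tailed
range, localities holding their own fungal species pools, and observed
co-occurring communities sampled inside single localities.

The key dial is ``pool_sharing``: the probability that each host draw for
a plant comes from the union of its localities' fungal pools rather than
from the full OTU pool. At high values, plants from the same locality
share hosts far more than chance, which propagates through the pipeline
as (i) higher host overlap for same-location groups and (ii) a positive
association between group host diversity and group overlap. At 0 the
location structure is inert and host sets are exchangeable across
localities.

One global seed drives every draw through a numpy ``SeedSequence``
splitting scheme, so each sub-generator (tree, localities, pools, hosts,
specimens, communities) is independently reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .errors import ConfigError
from .io import (
    CommunitySet,
    HostIncidence,
    PlantMetadata,
    write_communities,
    write_incidence,
    write_metadata,
    write_newick,
)
from .tree import PhyloTree

import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_tree", "generate_dataset", "write_fixture"]

FAMILIES = ("Burmanniaceae", "Gentianaceae", "Triuridaceae")


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters. Defaults mirror the survey being emulated:

    20 plant species, 138 fungal OTUs, host counts spanning 2-42, 15
    localities of which 9 hold more than one species, and observed
    communities of sizes {2: 2, 3: 3, 5: 1}.
    """

    seed: int = 0
    n_fungi: int = 138
    n_plants: int = 20
    n_localities: int = 15
    multi_species_localities: int = 9
    host_count_range: tuple[int, int] = (2, 42)
    tree_model: str = "yule"  # yule | coalescent
    locality_pool_size: int = 20
    pool_sharing: float = 0.9
    specimens_per_species_range: tuple[int, int] = (1, 10)
    communities_spec: dict[int, int] = field(
        default_factory=lambda: {2: 2, 3: 3, 5: 1}
    )
    clumped_pools: bool = False  # draw locality pools as phylogenetic clades
    mean_extra_localities: float = 0.3  # Poisson mean of localities beyond the first

    def validate(self) -> None:
        lo, hi = self.host_count_range
        if not (1 <= lo <= hi <= self.n_fungi):
            raise ConfigError("host_count_range must lie within [1, n_fungi]")
        if not 0.0 <= self.pool_sharing <= 1.0:
            raise ConfigError("pool_sharing must be in [0, 1]")
        if self.pool_sharing >= 1.0 and self.locality_pool_size < hi:
            # with pool_sharing < 1 draws can fall back to the regional pool,
            # so small local pools stay feasible
            raise ConfigError(
                "locality pool smaller than the largest host count: a "
                "single-locality plant could not fill its host set"
            )
        if self.locality_pool_size > self.n_fungi:
            raise ConfigError("locality pool cannot exceed the fungal pool")
        if not 0 <= self.multi_species_localities <= self.n_localities:
            raise ConfigError("multi_species_localities out of range")
        if self.n_plants < 2 or self.n_fungi < 2 or self.n_localities < 1:
            raise ConfigError("counts must be positive (>=2 species and fungi)")
        sizes = sorted(self.communities_spec, reverse=True)
        if sizes and sizes[0] > self.n_plants:
            raise ConfigError("community size exceeds the number of species")
        n_comm = sum(self.communities_spec.values())
        if n_comm > 0 and self.multi_species_localities == 0:
            raise ConfigError("communities require multi-species localities")
        if self.tree_model not in ("yule", "coalescent"):
            raise ConfigError(f"unknown tree model {self.tree_model!r}")
        sp_lo, sp_hi = self.specimens_per_species_range
        if not 1 <= sp_lo <= sp_hi:
            raise ConfigError("specimens_per_species_range must be >= 1")


@dataclass
class SyntheticDataset:
    tree: PhyloTree                # fungal-host phylogeny
    incidence: HostIncidence
    metadata: PlantMetadata
    communities: CommunitySet      # plays the role of observed field communities
    plant_tree: PhyloTree          # plant phylogeny (for the Mantel tests)
    config: SyntheticConfig


def _sub_seed(ss: np.random.SeedSequence, index: int) -> int:
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % 2**31)


def _simulate_ultrametric(n_leaves: int, model: str, seed: int, prefix: str) -> PhyloTree:
    rng = random.Random(seed)
    if model == "yule":
        dtree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves, rng=rng
        )
    else:
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
        dtree = treesim.pure_kingman_tree(taxon_namespace=taxa, pop_size=1, rng=rng)
    width = len(str(n_leaves))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"{prefix}{i + 1:0{width}d}"
    # force exact ultrametricity: stretch pendant edges to the deepest tip
    depths = {lf: lf.distance_from_root() for lf in dtree.leaf_node_iter()}
    maxd = max(depths.values())
    for lf, d in depths.items():
        lf.edge.length = (lf.edge.length or 0.0) + (maxd - d)
    return PhyloTree.from_dendropy(dtree)


def generate_tree(cfg: SyntheticConfig, seed: int | None = None) -> PhyloTree:
    """Random ultrametric fungal phylogeny with uniquely labelled OTU leaves."""
    cfg.validate()
    if seed is None:
        seed = _sub_seed(np.random.SeedSequence(cfg.seed), 0)
    return _simulate_ultrametric(cfg.n_fungi, cfg.tree_model, seed, "OTU_")


def _log_uniform_count(rng: np.random.Generator, lo: int, hi: int) -> int:
    v = int(np.floor(np.exp(rng.uniform(log(lo), log(hi + 1)))))
    return int(np.clip(v, lo, hi))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate a full, cross-consistent dataset under the configured regime."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(7)
    tree = _simulate_ultrametric(
        cfg.n_fungi, cfg.tree_model, int(seeds[0].generate_state(1)[0] % 2**31), "OTU_"
    )
    plant_tree = _simulate_ultrametric(
        cfg.n_plants, cfg.tree_model, int(seeds[1].generate_state(1)[0] % 2**31), "plant_"
    )
    rng_struct = np.random.default_rng(seeds[2])
    rng_pools = np.random.default_rng(seeds[3])
    rng_hosts = np.random.default_rng(seeds[4])
    rng_spec = np.random.default_rng(seeds[5])
    rng_comm = np.random.default_rng(seeds[6])

    plants = sorted(plant_tree.leaf_labels)
    fungi = sorted(tree.leaf_labels)
    wloc = len(str(cfg.n_localities))
    localities = [f"L{i + 1:0{wloc}d}" for i in range(cfg.n_localities)]
    multi = list(localities[: cfg.multi_species_localities])
    single = list(localities[cfg.multi_species_localities :])

    # --- species-locality structure ------------------------------------ #
    species_at: dict[str, set[str]] = {loc: set() for loc in localities}
    # single-species localities: one species each, distinct while possible
    anchor_pool = list(plants)
    rng_struct.shuffle(anchor_pool)
    for i, loc in enumerate(single):
        sp = anchor_pool[i % len(anchor_pool)]
        species_at[loc].add(sp)

    # multi-species localities: sizes >= 2, bumped to fit requested communities
    if multi:
        sizes = rng_struct.integers(2, min(6, cfg.n_plants) + 1, size=len(multi))
        required = sorted(
            (s for s, c in cfg.communities_spec.items() for _ in range(c)),
            reverse=True,
        )
        if len(required) > len(multi):
            raise ConfigError("more communities requested than multi-species localities")
        for i, s in enumerate(required):
            sizes[i] = max(sizes[i], s)
        for loc, size in zip(multi, sizes):
            chosen = rng_struct.choice(cfg.n_plants, size=int(size), replace=False)
            species_at[loc].update(plants[c] for c in chosen)

    # every species needs a locality
    covered = set().union(*species_at.values())
    for sp in plants:
        if sp not in covered:
            loc = multi[int(rng_struct.integers(len(multi)))] if multi else single[0]
            species_at[loc].add(sp)

    # extra locality memberships (species occur in several localities)
    if cfg.mean_extra_localities > 0 and multi:
        for sp in plants:
            extra = int(rng_struct.poisson(cfg.mean_extra_localities))
            for _ in range(extra):
                loc = multi[int(rng_struct.integers(len(multi)))]
                species_at[loc].add(sp)

    # --- locality fungal pools ------------------------------------------ #
    pools: dict[str, list[str]] = {}
    D = tree.patristic_matrix if cfg.clumped_pools else None
    for loc in localities:
        if cfg.clumped_pools:
            centre = int(rng_pools.integers(cfg.n_fungi))
            order = np.argsort(D[centre])
            idx = order[: cfg.locality_pool_size]
        else:
            idx = rng_pools.choice(cfg.n_fungi, size=cfg.locality_pool_size, replace=False)
        pools[loc] = [fungi[i] for i in sorted(idx)]

    # --- host sets ------------------------------------------------------ #
    lo, hi = cfg.host_count_range
    fungus_col = {f: j for j, f in enumerate(fungi)}
    matrix = np.zeros((len(plants), len(fungi)), dtype=np.int8)
    for pi, sp in enumerate(plants):
        my_locs = sorted(loc for loc in localities if sp in species_at[loc])
        pool = sorted(set().union(*(pools[loc] for loc in my_locs)))
        d_i = _log_uniform_count(rng_hosts, lo, hi)
        chosen: set[str] = set()
        while len(chosen) < d_i:
            source = pool if rng_hosts.random() < cfg.pool_sharing else fungi
            avail = [f for f in source if f not in chosen]
            if not avail:
                avail = [f for f in fungi if f not in chosen]
            chosen.add(avail[int(rng_hosts.integers(len(avail)))])
        for f in chosen:
            matrix[pi, fungus_col[f]] = 1
    incidence = HostIncidence(plants, fungi, matrix)

    # --- metadata -------------------------------------------------------- #
    sp_lo, sp_hi = cfg.specimens_per_species_range
    fam_of = {sp: FAMILIES[int(rng_spec.integers(len(FAMILIES)))] for sp in plants}
    rows = []
    for loc in localities:
        for sp in sorted(species_at[loc]):
            rows.append(
                {
                    "species": sp,
                    "family": fam_of[sp],
                    "locality": loc,
                    "n_specimens": int(rng_spec.integers(sp_lo, sp_hi + 1)),
                }
            )
    metadata = PlantMetadata(pd.DataFrame(rows))

    # --- observed communities (same-locality subsets) --------------------- #
    members: dict[str, list[str]] = {}
    seen: set[frozenset[str]] = set()
    cid = 0
    for size in sorted(cfg.communities_spec, reverse=True):
        for _ in range(cfg.communities_spec[size]):
            eligible = [loc for loc in multi if len(species_at[loc]) >= size]
            if not eligible:
                raise ConfigError(f"no locality can host a community of {size} species")
            for _attempt in range(200):
                loc = eligible[int(rng_comm.integers(len(eligible)))]
                sps = sorted(species_at[loc])
                pick = rng_comm.choice(len(sps), size=size, replace=False)
                group = frozenset(sps[i] for i in pick)
                if group not in seen:
                    break
            seen.add(group)
            cid += 1
            members[f"community_{cid:02d}"] = sorted(group)
    communities = CommunitySet(members, provenance="observed")

    return SyntheticDataset(
        tree=tree,
        incidence=incidence,
        metadata=metadata,
        communities=communities,
        plant_tree=plant_tree,
        config=cfg,
    )


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the dataset as the pipeline's input file-set; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "fungal_tree.nwk",
        "plant_tree": out / "plant_tree.nwk",
        "incidence": out / "incidence.tsv",
        "metadata": out / "metadata.tsv",
        "communities": out / "communities.tsv",
    }
    write_newick(dataset.tree, paths["tree"])
    write_newick(dataset.plant_tree, paths["plant_tree"])
    write_incidence(dataset.incidence, paths["incidence"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_communities(dataset.communities, paths["communities"])
    return paths
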