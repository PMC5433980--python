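"""End-to-end analysis: per-plant scaled PD, Mantel tests, group ensembles,
correlations and same-location comparisons, returned as one report object.

Stages (in order):

1. cross-validation of the four inputs (hard failure if inconsistent);
2. per-plant host-set PD with exact size-class extremes and scaled PD;
3. Mantel tests of plant phylogenetic distance against host-count
   dissimilarity, Bray-Curtis and host overlap — globally and within each
   multi-species locality (requires a plant phylogeny; skipped without one);
4. exhaustive group ensembles for each requested size, with combined PD,
   mean pairwise overlap, covariates, location flags and min-max scaling
   within each same-size ensemble;
5. Pearson and partial Pearson correlations (scaled PD vs scaled overlap)
   per size and pooled, the partial form controlling for total specimens,
   distinct OTUs and the Herfindahl concentration of specimens;
6. observed communities scaled against their same-size generated ensemble;
7. Welch comparisons of scaled PD and scaled overlap between same-location
   and mixed-location groups, per size.

Reports are deterministic given (inputs, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensembles import (
    Ensemble,
    GroupRecord,
    enumerate_groups,
    evaluate_groups,
    scale_against,
    scale_within_ensemble,
)
from .errors import ValidationError
from .io import CommunitySet, HostIncidence, PlantMetadata, cross_validate
from .overlap import pairwise_matrix
from .phylo import faith_pd, pd_extremes
from .stats import mantel, partial_pearson, pearson, phylo_distance_matrix, welch_t
from .tree import PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "AnalysisReport", "run_analysis", "report_tables"]

MANTEL_MEASURES = ("count-dissimilarity", "bray-curtis", "min-overlap")


@dataclass(frozen=True)
class AnalysisParams:
    n_perm: int = 10_000
    seed: int = 0
    group_sizes: tuple[int, ...] = (2, 3, 4, 5)


@dataclass
class AnalysisReport:
    per_plant: pd.DataFrame
    mantel: pd.DataFrame
    correlations: pd.DataFrame
    location_pd: pd.DataFrame
    location_overlap: pd.DataFrame
    observed: pd.DataFrame
    ensembles: dict[int, Ensemble]
    meta: dict = field(default_factory=dict)

    def has_degenerate(self) -> bool:
        flags = []
        if "degenerate" in self.mantel.columns and len(self.mantel):
            flags.append(bool(self.mantel["degenerate"].any()))
        if "degenerate" in self.correlations.columns and len(self.correlations):
            flags.append(bool(self.correlations["degenerate"].any()))
        return any(flags)

    def to_json(self) -> str:
        def frame(df: pd.DataFrame):
            clean = df.replace({np.nan: None})
            return clean.to_dict(orient="records")

        payload = {
            "meta": self.meta,
            "per_plant": frame(self.per_plant),
            "mantel": frame(self.mantel),
            "correlations": frame(self.correlations),
            "location_scaled_pd": frame(self.location_pd),
            "location_scaled_overlap": frame(self.location_overlap),
            "observed_communities": frame(self.observed),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def run_analysis(
    tree: PhyloTree,
    incidence: HostIncidence,
    metadata: PlantMetadata,
    communities: CommunitySet | None = None,
    params: AnalysisParams | None = None,
    plant_tree: PhyloTree | None = None,
) -> AnalysisReport:
    """Execute all stages and return the complete report."""
    params = params or AnalysisParams()
    t0 = time.perf_counter()

    report = cross_validate(tree, incidence, metadata, communities)
    if not report.is_empty():
        raise ValidationError(
            "inconsistent inputs:\n" + "\n".join(report.entries())
        )
    tree.check_ultrametric()

    per_plant = _per_plant_table(tree, incidence)
    logger.info("per-plant PD: %d plants (%.2fs)", len(per_plant), time.perf_counter() - t0)

    mantel_df = _mantel_tables(tree, incidence, metadata, params, plant_tree)

    ensembles: dict[int, Ensemble] = {}
    sizes = sorted(set(params.group_sizes))
    needed = set(sizes)
    if communities is not None:
        needed |= {len(m) for _, m in communities}
    for n in sorted(needed):
        t1 = time.perf_counter()
        ens = enumerate_groups(incidence.plant_ids, n)
        evaluate_groups(ens.records, tree, incidence, metadata)
        scale_within_ensemble(ens)
        ensembles[n] = ens
        logger.info("ensemble n=%d: %d groups (%.2fs)", n, len(ens), time.perf_counter() - t1)

    correlations = _correlation_table(ensembles, sizes)
    observed_df = _observed_table(tree, incidence, metadata, communities, ensembles, correlations)
    loc_pd, loc_ov = _location_tables(ensembles, sizes)

    meta = {
        "seed": params.seed,
        "n_perm": params.n_perm,
        "group_sizes": list(sizes),
        "n_plants": len(incidence.plant_ids),
        "n_fungi": len(incidence.fungus_ids),
        "has_plant_tree": plant_tree is not None,
        "version": __version__,
    }
    return AnalysisReport(
        per_plant=per_plant,
        mantel=mantel_df,
        correlations=correlations,
        location_pd=loc_pd,
        location_overlap=loc_ov,
        observed=observed_df,
        ensembles=ensembles,
        meta=meta,
    )


# ---------------------------------------------------------------------- #
# stage helpers
# ---------------------------------------------------------------------- #


def _per_plant_table(tree: PhyloTree, inc: HostIncidence) -> pd.DataFrame:
    d = inc.d
    k_max = int(d.max())
    lo, hi = pd_extremes(tree, k_max)
    rows = []
    for plant, k in zip(inc.plant_ids, d):
        hosts = inc.host_set(plant)
        pdv = faith_pd(tree, hosts)
        k = int(k)
        denom = hi[k] - lo[k]
        scaled = None if denom <= 0 else (pdv - lo[k]) / denom
        rows.append(
            {
                "plant_id": plant,
                "d": k,
                "pd": pdv,
                "pd_min": float(lo[k]),
                "pd_max": float(hi[k]),
                "scaled_pd": scaled,
            }
        )
    return pd.DataFrame(rows)


def _mantel_tables(
    tree: PhyloTree,
    inc: HostIncidence,
    meta: PlantMetadata,
    params: AnalysisParams,
    plant_tree: PhyloTree | None,
) -> pd.DataFrame:
    rows: list[dict] = []
    if plant_tree is None:
        return pd.DataFrame(
            columns=["scope", "measure", "r", "p", "n", "n_perm", "degenerate"]
        )
    scopes: list[tuple[str, list[str]]] = [("global", list(inc.plant_ids))]
    present = set(inc.plant_ids)
    for loc in meta.multi_species_localities():
        sp = sorted(meta.species_at(loc) & present)
        if len(sp) >= 3:  # Mantel needs >= 3 taxa
            scopes.append((loc, sp))

    seed_seq = np.random.SeedSequence(params.seed)
    seeds = seed_seq.spawn(len(scopes) * len(MANTEL_MEASURES))
    si = 0
    for scope, species in scopes:
        dphy = phylo_distance_matrix(plant_tree, species)
        sub = _subset_incidence(inc, species)
        for measure in MANTEL_MEASURES:
            mat = pairwise_matrix(sub, measure)
            res = mantel(
                dphy, mat, n_perm=params.n_perm,
                seed=int(seeds[si].generate_state(1)[0] % 2**31),
            )
            si += 1
            rows.append(
                {
                    "scope": scope,
                    "measure": measure,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "n_perm": res.n_perm,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


def _subset_incidence(inc: HostIncidence, species: list[str]) -> HostIncidence:
    rows = [inc.row(p) for p in species]
    return HostIncidence(species, inc.fungus_ids, inc.matrix[rows])


def _scaled_arrays(records: list[GroupRecord]):
    ok = [
        r
        for r in records
        if r.scaled_pd is not None and r.scaled_overlap is not None
    ]
    if not ok:
        return np.array([]), np.array([]), np.empty((0, 3))
    x = np.array([r.scaled_overlap for r in ok])
    y = np.array([r.scaled_pd for r in ok])
    Z = np.array([[r.total_specimens, r.total_otus, r.herfindahl] for r in ok], dtype=float)
    return x, y, Z


def _corr_rows(scope: str, x, y, Z) -> list[dict]:
    from .stats import CorrResult

    out = []
    for kind, n_cov in (("raw", 0), ("partial", Z.shape[1] if Z.ndim == 2 else 1)):
        try:
            res = pearson(x, y) if kind == "raw" else partial_pearson(x, y, Z)
        except Exception:  # too few / constant groups: report as degenerate
            res = CorrResult(np.nan, np.nan, max(len(x) - 2 - n_cov, 0),
                             n_covariates=n_cov, degenerate=True)
        out.append(
            {
                "scope": scope,
                "kind": kind,
                "r": res.r,
                "p": res.p,
                "df": res.df,
                "n_covariates": res.n_covariates,
                "n_groups": len(x),
                "degenerate": res.degenerate,
            }
        )
    return out


def _correlation_table(ensembles: dict[int, Ensemble], sizes: list[int]) -> pd.DataFrame:
    rows = []
    pooled: list[GroupRecord] = []
    for n in sizes:
        recs = ensembles[n].records
        pooled.extend(recs)
        rows.extend(_corr_rows(f"size_{n}", *_scaled_arrays(recs)))
    rows.extend(_corr_rows("pooled", *_scaled_arrays(pooled)))
    return pd.DataFrame(rows)


def _observed_table(
    tree: PhyloTree,
    inc: HostIncidence,
    meta: PlantMetadata,
    communities: CommunitySet | None,
    ensembles: dict[int, Ensemble],
    correlations: pd.DataFrame,
) -> pd.DataFrame:
    if communities is None or len(communities) == 0:
        return pd.DataFrame(
            columns=[
                "community_id", "members", "n", "combined_pd", "overlap",
                "scaled_pd", "scaled_overlap", "same_location",
            ]
        )
    rows = []
    for cid, members in communities:
        rec = GroupRecord(members=tuple(sorted(members)), provenance="observed")
        evaluate_groups([rec], tree, inc, meta)
        scale_against([rec], ensembles[rec.n])
        rows.append(
            {
                "community_id": cid,
                "members": ";".join(rec.members),
                "n": rec.n,
                "combined_pd": rec.combined_pd,
                "overlap": rec.overlap,
                "scaled_pd": rec.scaled_pd,
                "scaled_overlap": rec.scaled_overlap,
                "same_location": rec.same_location,
            }
        )
    df = pd.DataFrame(rows)
    ok = df.dropna(subset=["scaled_pd", "scaled_overlap"])
    if len(ok) >= 3:
        res = pearson(ok["scaled_overlap"], ok["scaled_pd"])
        correlations.loc[len(correlations)] = {
            "scope": "observed",
            "kind": "raw",
            "r": res.r,
            "p": res.p,
            "df": res.df,
            "n_covariates": 0,
            "n_groups": len(ok),
            "degenerate": res.degenerate,
        }
    return df


def _location_tables(ensembles: dict[int, Ensemble], sizes: list[int]):
    pd_rows, ov_rows = [], []
    for n in sizes:
        recs = ensembles[n].records
        for attr, rows in (("scaled_pd", pd_rows), ("scaled_overlap", ov_rows)):
            same = [getattr(r, attr) for r in recs if r.same_location and getattr(r, attr) is not None]
            diff = [getattr(r, attr) for r in recs if not r.same_location and getattr(r, attr) is not None]
            if len(same) >= 2 and len(diff) >= 2:
                res = welch_t(same, diff)
                rows.append(
                    {
                        "size": n,
                        "mean_same": res.mean_a,
                        "mean_different": res.mean_b,
                        "n_same": len(same),
                        "n_different": len(diff),
                        "t": res.t,
                        "p": res.p,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                    }
                )
            else:
                rows.append(
                    {
                        "size": n,
                        "mean_same": float(np.mean(same)) if same else None,
                        "mean_different": float(np.mean(diff)) if diff else None,
                        "n_same": len(same),
                        "n_different": len(diff),
                        "t": None,
                        "p": None,
                        "ci_low": None,
                        "ci_high": None,
                    }
                )
    return pd.DataFrame(pd_rows), pd.DataFrame(ov_rows)


# ---------------------------------------------------------------------- #
# export
# ---------------------------------------------------------------------- #


def report_tables(report: AnalysisReport, out_dir) -> dict[str, Path]:
    """Write one TSV per result table plus the JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def dump(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    dump("per_plant", report.per_plant)
    dump("mantel", report.mantel)
    dump("correlations", report.correlations)
    dump("location_scaled_pd", report.location_pd)
    dump("location_scaled_overlap", report.location_overlap)
    dump("observed_communities", report.observed)
    for n, ens in report.ensembles.items():
        dump(f"groups_n{n}", ens.to_frame())
    summary = out / "summary.json"
    summary.write_text(report.to_json() + "\n", encoding="utf-8")
    paths["summary"] = summary
    return paths
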