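"""Permutation Mantel tests, (partial) Pearson correlation, Welch's t.

The Mantel statistic is the Pearson correlation between the upper
triangles of two symmetric matrices; significance comes from jointly
permuting the rows and columns of one matrix (the other stays fixed),
with the one-sided "greater" p-value (count + 1) / (n_perm + 1), the
convention of vegan's ``mantel``. Permutations are vectorised and fully
seed-controlled, so results are bit-reproducible.

Partial correlation uses the residual method: x and y are projected on
the covariates plus an intercept, and the residuals are correlated, with
df = n - 2 - n_covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError
from .overlap import PairwiseMatrix
from .tree import PhyloTree

__all__ = [
    "MantelResult",
    "CorrResult",
    "TTestResult",
    "mantel",
    "phylo_distance_matrix",
    "pearson",
    "partial_pearson",
    "welch_t",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    n: int
    seed: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    df: int
    n_covariates: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


# ---------------------------------------------------------------------- #
# Mantel
# ---------------------------------------------------------------------- #


def mantel(
    dist_a: PairwiseMatrix,
    dist_b: PairwiseMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MantelResult:
    """One-sided permutation Mantel test between two plant-pair matrices."""
    if dist_a.plant_ids != dist_b.plant_ids:
        raise DomainError("matrices must share the same plant ordering")
    n = dist_a.n
    if n < 3:
        raise DomainError("Mantel test needs at least three plants")
    A, B = dist_a.values, dist_b.values
    iu = np.triu_indices(n, 1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        return MantelResult(np.nan, np.nan, n_perm, n, seed, degenerate=True)

    r_obs = _pearson_r(a, b)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Bp = B[perms[:, :, None], perms[:, None, :]]  # (n_perm, n, n)
    bp = Bp[:, iu[0], iu[1]]
    az = (a - a.mean()) / a.std()
    bz = (bp - bp.mean(axis=1, keepdims=True)) / bp.std(axis=1, keepdims=True)
    r_perm = (bz @ az) / len(a)
    p = (np.count_nonzero(r_perm >= r_obs) + 1) / (n_perm + 1)
    return MantelResult(float(r_obs), float(p), n_perm, n, seed)


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    return float((xz * yz).mean())


def phylo_distance_matrix(tree: PhyloTree, taxa: Sequence[str]) -> PairwiseMatrix:
    """Patristic (path-length) distances between the given tree leaves."""
    cols = tree.leaf_ids(taxa)
    D = tree.patristic_matrix[np.ix_(cols, cols)]
    return PairwiseMatrix(list(taxa), D, "count-dissimilarity")


# ---------------------------------------------------------------------- #
# correlations
# ---------------------------------------------------------------------- #


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrResult:
    """Product-moment correlation with two-sided t-distribution p, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("pearson needs two equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        return CorrResult(np.nan, np.nan, len(x) - 2, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrResult(float(r), float(p), df=len(x) - 2)


def partial_pearson(
    x: Sequence[float], y: Sequence[float], covariates: np.ndarray
) -> CorrResult:
    """Correlation of x and y after removing a linear effect of the covariates.

    df = n - 2 - n_covariates; with an empty covariate matrix this reduces
    exactly to :func:`pearson`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.size == 0:
        return pearson(x, y)
    n, g = Z.shape
    if len(x) != n or len(y) != n:
        raise DomainError("covariate rows must match x and y")
    if n <= g + 2:
        raise DomainError("too few observations for the covariate count")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DomainError("rank-deficient covariate matrix")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    df = n - 2 - g
    # residuals that are numerically zero relative to the input scale mean
    # the variable is (an affine function of) the covariates: no partial
    # correlation is defined
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if rx.std() <= tol_x or ry.std() <= tol_y:
        return CorrResult(np.nan, np.nan, df, n_covariates=g, degenerate=True)
    r = _pearson_r(rx, ry)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrResult(r, p, df=df, n_covariates=g)


# ---------------------------------------------------------------------- #
# two-sample comparison
# ---------------------------------------------------------------------- #


def welch_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance t-test with the 95% CI of mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each sample needs at least two observations")
    if a.std() == 0 and b.std() == 0:
        diff = float(a.mean() - b.mean())
        return TTestResult(
            float(a.mean()), float(b.mean()), np.nan, np.nan, diff, diff,
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return TTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(res.statistic),
        p=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )
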