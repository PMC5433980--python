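import numpy as np
import pytest

from mycoverlap import (
    DomainError,
    PhyloTree,
    mantel,
    partial_pearson,
    pearson,
    phylo_distance_matrix,
    welch_t,
)
from mycoverlap.overlap import PairwiseMatrix


def sym_matrix(rng, n, ids=None):
    x = rng.random((n, n))
    m = (x + x.T) / 2
    np.fill_diagonal(m, 0.0)
    return PairwiseMatrix(ids or [f"p{i}" for i in range(n)], m, "bray-curtis")


class TestMantel:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(1)
        a = sym_matrix(rng, 8)
        res = mantel(a, a, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p >= 1 / 100

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a = sym_matrix(rng, 8)
        b = PairwiseMatrix(a.plant_ids, 2.0 * a.values, a.measure)
        assert mantel(a, b, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_seed_reproducibility_bit_identical(self):
        rng = np.random.default_rng(3)
        a, b = sym_matrix(rng, 10), sym_matrix(rng, 10)
        r1 = mantel(a, b, n_perm=499, seed=11)
        r2 = mantel(a, b, n_perm=499, seed=11)
        assert r1 == r2

    def test_p_floor(self):
        rng = np.random.default_rng(4)
        a, b = sym_matrix(rng, 9), sym_matrix(rng, 9)
        res = mantel(a, b, n_perm=199, seed=0)
        assert res.p >= 1 / 200

    def test_degenerate_constant_matrix(self):
        ids = ["a", "b", "c"]
        const = PairwiseMatrix(ids, np.zeros((3, 3)), "bray-curtis")
        rng = np.random.default_rng(5)
        res = mantel(const, sym_matrix(rng, 3, ids), n_perm=99, seed=0)
        assert res.degenerate

    def test_label_mismatch(self):
        rng = np.random.default_rng(6)
        a = sym_matrix(rng, 5)
        b = sym_matrix(rng, 5, ids=[f"q{i}" for i in range(5)])
        with pytest.raises(DomainError):
            mantel(a, b)

    def test_against_scikit_bio(self):
        """Independent cross-check: r exact, permutation p within Monte-Carlo
        tolerance of scikit-bio's one-sided Mantel."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(7)
        n = 12
        base = rng.random((n, n))
        a_vals = (base + base.T) / 2
        np.fill_diagonal(a_vals, 0)
        noise = rng.random((n, n)) * 0.3
        b_vals = a_vals + (noise + noise.T) / 2
        np.fill_diagonal(b_vals, 0)
        ids = [f"p{i}" for i in range(n)]
        ours = mantel(
            PairwiseMatrix(ids, a_vals, "bray-curtis"),
            PairwiseMatrix(ids, b_vals, "bray-curtis"),
            n_perm=9999,
            seed=1,
        )
        r_sk, p_sk, _ = skbio_mantel(
            DistanceMatrix(a_vals, ids),
            DistanceMatrix(b_vals, ids),
            method="pearson",
            permutations=9999,
            alternative="greater",
            seed=2,
        )
        assert ours.r == pytest.approx(float(r_sk), abs=1e-10)
        assert ours.p == pytest.approx(float(p_sk), abs=0.02)


class TestPhyloDistances:
    def test_cherry(self):
        t = PhyloTree.from_newick("(A:1,B:1);")
        m = phylo_distance_matrix(t, ["A", "B"])
        assert m.values[0, 1] == pytest.approx(2.0)
        assert m.values[0, 0] == 0.0

    def test_four_leaf_fixture(self, tree4):
        m = phylo_distance_matrix(tree4, ["A", "C"])
        assert m.values[0, 1] == pytest.approx(4.0)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_against_direct_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        y = 0.6 * x + rng.normal(size=25)
        res = pearson(x, y)
        r_direct = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        assert res.df == 23

    def test_constant_input_degenerate(self):
        res = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate


class TestPartialPearson:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=20), rng.normal(size=20)
        full = pearson(x, y)
        part = partial_pearson(x, y, np.empty((20, 0)))
        assert part.r == pytest.approx(full.r)
        assert part.df == full.df

    def test_linear_function_of_covariates_gives_zero(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        y = 2.0 * z + 1.0  # y is exactly linear in the covariate
        res = partial_pearson(x, y, z)
        assert res.degenerate or abs(res.r) < 1e-8

    def test_one_covariate_recursion_formula(self):
        """Residual-method partial r must match the closed-form recursion
        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        rng = np.random.default_rng(11)
        z = rng.normal(size=40)
        x = 0.5 * z + rng.normal(size=40)
        y = -0.3 * z + rng.normal(size=40)
        r_xy = pearson(x, y).r
        r_xz = pearson(x, z).r
        r_yz = pearson(y, z).r
        expected = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2)
        )
        res = partial_pearson(x, y, z)
        assert res.r == pytest.approx(expected, abs=1e-10)
        assert res.df == 40 - 3

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=15)
        Z = np.column_stack([z, 2 * z])
        with pytest.raises(DomainError):
            partial_pearson(rng.normal(size=15), rng.normal(size=15), Z)


class TestWelch:
    def test_equal_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(a, a)
        assert res.t == pytest.approx(0.0)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_against_direct_formula(self):
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2])
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_direct = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_direct = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        from scipy.stats import t as tdist

        assert res.t == pytest.approx(float(t_direct), abs=1e-12)
        assert res.p == pytest.approx(
            float(2 * tdist.sf(abs(t_direct), df_direct)), abs=1e-12
        )
        half = tdist.ppf(0.975, df_direct) * np.sqrt(va + vb)
        assert res.ci_low == pytest.approx(a.mean() - b.mean() - half, abs=1e-9)
        assert res.ci_high == pytest.approx(a.mean() - b.mean() + half, abs=1e-9)

    def test_ci_brackets_true_shift(self):
        rng = np.random.default_rng(13)
        a = rng.normal(loc=0.5, size=4000)
        b = rng.normal(loc=0.0, size=4000)
        res = welch_t(a, b)
        assert res.ci_low <= 0.5 <= res.ci_high
        assert res.ci_high - res.ci_low < 0.15

    def test_invariant_ci_contains_mean_difference(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=10), rng.normal(size=12)
        res = welch_t(a, b)
        assert res.ci_low <= res.mean_a - res.mean_b <= res.ci_high
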