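import numpy as np
import pytest
import scipy.linalg

from ecomorph import io_formats as iof
from ecomorph import phylo_stats as ps
from ecomorph.synthetic_data import simulate_tree


@pytest.fixture
def five_tip_cov():
    tree = iof.grafen_branch_lengths(iof.read_newick("(((A,B),(C,D)),E);"))
    return iof.phylo_vcv(tree)


# ---------------------------------------------------------------------------
# independent oracles


def ordinary_pls_first_r(X, Y):
    """Brute-force non-phylogenetic two-block PLS first-pair correlation."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    R = Xc.T @ Yc / (X.shape[0] - 1)
    U, _, Vt = np.linalg.svd(R, full_matrices=False)
    xs = Xc @ U[:, 0]
    ys = Yc @ Vt[0]
    return np.corrcoef(xs, ys)[0, 1]


def classical_anova_f(y, groups):
    """Closed-form one-way ANOVA F."""
    y = np.asarray(y, dtype=float)
    levels = sorted(set(groups))
    grand = y.mean()
    ssb = sum(
        (groups == lev).sum() * (y[groups == lev].mean() - grand) ** 2
        for lev in levels
    )
    ssw = sum(((y[groups == lev] - y[groups == lev].mean()) ** 2).sum() for lev in levels)
    k, n = len(levels), len(y)
    return (ssb / (k - 1)) / (ssw / (n - k))


def blomberg_k_oracle(y, C):
    """Univariate Kappa statistic via Cholesky whitening and explicit GLS."""
    n = len(y)
    L = scipy.linalg.cholesky(C, lower=True)
    Linv = scipy.linalg.solve_triangular(L, np.eye(n), lower=True)
    ones_w = Linv @ np.ones(n)
    y_w = Linv @ y
    ahat = float(ones_w @ y_w / (ones_w @ ones_w))  # GLS root state
    dev = y - ahat
    mse0 = dev @ dev / (n - 1)
    dev_w = Linv @ dev
    mse = dev_w @ dev_w / (n - 1)
    Cinv = Linv.T @ Linv
    expected = (np.trace(C) - n / np.ones(n).dot(Cinv).dot(np.ones(n))) / (n - 1)
    return (mse0 / mse) / expected


# ---------------------------------------------------------------------------
# GLS building blocks


class TestGlsMean:
    def test_identity_is_column_mean(self, rng):
        Y = rng.normal(size=(8, 3))
        np.testing.assert_allclose(
            ps.phylo_gls_mean(Y, np.eye(8)), Y.mean(axis=0), atol=1e-12
        )

    def test_constant_columns(self, five_tip_cov):
        Y = np.full((5, 2), 3.7)
        np.testing.assert_allclose(ps.phylo_gls_mean(Y, five_tip_cov.C), 3.7)

    def test_two_tips(self):
        a = ps.phylo_gls_mean(np.array([0.0, 2.0]), np.eye(2))
        assert a[0] == pytest.approx(1.0)


class TestPhyloTransform:
    def test_identity_centers(self, rng):
        Y = rng.normal(size=(10, 2))
        out = ps.phylo_transform(Y, np.eye(10))
        np.testing.assert_allclose(out, Y - Y.mean(axis=0), atol=1e-12)

    def test_whitening_property(self, rng):
        for _ in range(20):
            tree = simulate_tree(12, int(rng.integers(2**31)))
            C = iof.phylo_vcv(tree).C
            P = ps.inv_sqrt(C)
            np.testing.assert_allclose(P @ C @ P.T, np.eye(12), atol=1e-8)

    def test_ridge_warning(self):
        C = np.ones((3, 3))  # singular
        with pytest.warns(UserWarning, match="ridge"):
            ps.inv_sqrt(C)


# ---------------------------------------------------------------------------
# phylogenetic PLS


class TestPhyloPls:
    def test_same_block_r_is_one(self, rng, five_tip_cov):
        X = rng.normal(size=(5, 3))
        res = ps.phylo_pls(X, X.copy(), five_tip_cov.C, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_star_matches_ordinary_pls(self, rng):
        n = 10
        X = rng.normal(size=(n, 4))
        Y = rng.normal(size=(n, 6))
        res = ps.phylo_pls(X, Y, np.eye(n), n_perm=0)
        assert res.r == pytest.approx(ordinary_pls_first_r(X, Y), abs=1e-8)

    def test_loadings_unit_norm(self, rng, five_tip_cov):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 4))
        res = ps.phylo_pls(X, Y, five_tip_cov.C, n_perm=0)
        assert np.linalg.norm(res.x_loadings) == pytest.approx(1.0)
        assert np.linalg.norm(res.y_loadings) == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        n = 12
        tree = simulate_tree(n, 3)
        C = iof.phylo_vcv(tree).C
        X = rng.normal(size=(n, 4))
        Y = rng.normal(size=(n, 5))
        r0 = ps.phylo_pls(X, Y, C, n_perm=0).r
        Qx, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        Qy, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        r1 = ps.phylo_pls(X @ Qx, Y @ Qy, C, n_perm=0).r
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_min_p_value(self, rng, five_tip_cov):
        X = rng.normal(size=(5, 2))
        res = ps.phylo_pls(X, X.copy(), five_tip_cov.C, n_perm=99, seed=0)
        assert res.p >= 1 / 100

    def test_reproducible(self, rng):
        n = 10
        C = iof.phylo_vcv(simulate_tree(n, 1)).C
        X = rng.normal(size=(n, 3))
        Y = rng.normal(size=(n, 4))
        r1 = ps.phylo_pls(X, Y, C, n_perm=199, seed=7)
        r2 = ps.phylo_pls(X, Y, C, n_perm=199, seed=7)
        assert (r1.r, r1.z, r1.p) == (r2.r, r2.z, r2.p)

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            ps.phylo_pls(np.ones((2, 1)), np.ones((2, 1)), np.eye(2))


# ---------------------------------------------------------------------------
# phylogenetic signal


class TestPhysignal:
    def test_univariate_oracle(self, rng, five_tip_cov):
        y = np.array([0.3, -1.2, 0.8, 2.0, -0.4])
        res = ps.physignal(y, five_tip_cov.C, n_perm=0)
        assert res.K == pytest.approx(blomberg_k_oracle(y, five_tip_cov.C), abs=1e-10)
        assert res.scope == "univariate"

    def test_multivariate_oracle_random(self, rng):
        # Kmult on q traits equals the trace-form oracle computed per spec
        tree = simulate_tree(10, 11)
        C = iof.phylo_vcv(tree).C
        Y = rng.normal(size=(10, 3))
        res = ps.physignal(Y, C, n_perm=0)
        # brute force with explicit inverses
        Cinv = np.linalg.inv(C)
        a = np.ones(10) @ Cinv @ Y / (np.ones(10) @ Cinv @ np.ones(10))
        Yc = Y - a
        K = (np.trace(Yc.T @ Yc) / np.trace(Yc.T @ Cinv @ Yc)) / (
            (np.trace(C) - 10 / (np.ones(10) @ Cinv @ np.ones(10))) / 9
        )
        assert res.K == pytest.approx(K, abs=1e-10)
        assert res.scope == "multivariate"

    def test_star_tree_error(self):
        with pytest.raises(ValueError, match="star"):
            ps.physignal(np.arange(4.0), np.eye(4))

    def test_iid_data_low_k(self, rng):
        # i.i.d. data carries no signal: mean K well below 1
        ks = []
        for _ in range(100):
            tree = simulate_tree(30, int(rng.integers(2**31)))
            C = iof.phylo_vcv(tree).C
            ks.append(ps.physignal(rng.normal(size=(30, 1)), C, n_perm=0).K)
        assert np.mean(ks) < 0.8

    def test_reproducible(self, rng, five_tip_cov):
        y = rng.normal(size=5)
        a = ps.physignal(y, five_tip_cov.C, n_perm=199, seed=3)
        b = ps.physignal(y, five_tip_cov.C, n_perm=199, seed=3)
        assert (a.K, a.p) == (b.K, b.p)


# ---------------------------------------------------------------------------
# GLS MANOVA via randomized residuals


class TestRrppManova:
    def test_identity_univariate_matches_anova(self, rng):
        y = np.array([1.0, 1.3, 0.8, 3.1, 2.9, 3.3, 5.2, 5.0, 4.7])
        groups = np.repeat([1, 2, 3], 3)
        res = ps.rrpp_manova(y, groups, np.eye(9), n_perm=99, seed=0)
        assert res.f == pytest.approx(classical_anova_f(y, groups), abs=1e-10)

    def test_ss_additivity_and_rsq(self, rng):
        n = 20
        C = iof.phylo_vcv(simulate_tree(n, 4)).C
        Y = rng.normal(size=(n, 5))
        groups = np.repeat([1, 2, 3, 4], 5)
        res = ps.rrpp_manova(Y, groups, C, n_perm=99, seed=0)
        assert res.ss_term + res.ss_resid == pytest.approx(res.ss_total, rel=1e-10)
        assert res.rsq == pytest.approx(res.ss_term / res.ss_total)
        assert res.df_term + res.df_resid == res.df_total

    def test_strong_shift_significant(self, rng):
        n = 30
        C = iof.phylo_vcv(simulate_tree(n, 9)).C
        groups = np.repeat([1, 2], 15)
        Y = rng.normal(size=(n, 4))
        Y[groups == 2] += 5.0
        res = ps.rrpp_manova(Y, groups, C, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ps.rrpp_manova(np.ones((4, 1)), np.array([1, 1, 1, 2]), np.eye(4))

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ps.rrpp_manova(np.ones((4, 1)), np.ones(4), np.eye(4))

    def test_reproducible(self, rng):
        n = 12
        C = iof.phylo_vcv(simulate_tree(n, 5)).C
        Y = rng.normal(size=(n, 3))
        groups = np.repeat([1, 2, 3], 4)
        a = ps.rrpp_manova(Y, groups, C, n_perm=199, seed=13)
        b = ps.rrpp_manova(Y, groups, C, n_perm=199, seed=13)
        assert (a.f, a.z, a.p) == (b.f, b.z, b.p)


class TestPairwise:
    def test_two_groups_consistent_with_global(self, rng):
        n = 24
        C = iof.phylo_vcv(simulate_tree(n, 6)).C
        groups = np.repeat([1, 2], 12)
        Y = rng.normal(size=(n, 3))
        Y[groups == 2] += 1.5
        fit = ps.rrpp_manova(Y, groups, C, n_perm=999, seed=0)
        pw = ps.pairwise_group_tests(fit)
        assert len(pw.pairs) == 1
        assert pw.distances[0] >= 0
        assert abs(pw.p_values[0] - fit.p) < 0.05  # same contrast, same nulls

    def test_shifted_group_flagged(self, rng):
        # BM-consistent data, group labels shuffled relative to the tree
        n = 30
        C = iof.phylo_vcv(simulate_tree(n, 8)).C
        L = np.linalg.cholesky(C)
        groups = np.repeat([1, 2, 3], 10)
        rng.shuffle(groups)
        Y = L @ rng.normal(size=(n, 3))
        Y[groups == 3] += 6.0
        fit = ps.rrpp_manova(Y, groups, C, n_perm=999, seed=1)
        pw = ps.pairwise_group_tests(fit)
        pmap = {pair: p for pair, p in zip(pw.pairs, pw.p_values)}
        assert pmap[(1, 3)] < 0.05 and pmap[(2, 3)] < 0.05
        assert pmap[(1, 2)] > 0.05

    def test_null_p_moderate(self, rng):
        n = 20
        C = iof.phylo_vcv(simulate_tree(n, 2)).C
        groups = np.repeat([1, 2], 10)
        Y = rng.normal(size=(n, 3))
        fit = ps.rrpp_manova(Y, groups, C, n_perm=999, seed=5)
        pw = ps.pairwise_group_tests(fit)
        assert pw.p_values[0] > 0.01


class TestGroupMeansPca:
    def test_two_groups_on_pc1(self, rng):
        Y = rng.normal(size=(12, 2))
        groups = np.repeat([1, 2], 6)
        Y[groups == 2] += 3.0
        out = ps.group_means_pca(Y, groups, np.eye(12))
        np.testing.assert_allclose(out.rotated_means[:, 1], 0.0, atol=1e-10)

    def test_rotation_preserves_distances(self, rng):
        Y = rng.normal(size=(20, 4))
        groups = np.repeat([1, 2, 3, 4], 5)
        C = iof.phylo_vcv(simulate_tree(20, 3)).C
        out = ps.group_means_pca(Y, groups, C)
        P = ps.inv_sqrt(C)
        from ecomorph.phylo_stats import _design, _ls_means

        X, _ = _design(groups)
        means = _ls_means(P @ X, P @ Y, 4)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            pdist(out.rotated_means), pdist(means), atol=1e-8
        )

    def test_equal_groups_coincident(self):
        Y = np.tile(np.arange(4.0)[:, None], (3, 2))
        groups = np.repeat([1, 2, 3], 4)
        out = ps.group_means_pca(Y, groups, np.eye(12))
        np.testing.assert_allclose(
            out.rotated_means - out.rotated_means[0], 0.0, atol=1e-10
        )


class TestEcoProject:
    def test_axes_shape(self, rng):
        n = 15
        C = iof.phylo_vcv(simulate_tree(n, 1)).C
        X = rng.normal(size=(n, 4))
        Y = rng.normal(size=(n, 6))
        pls = ps.phylo_pls(X, Y, C, n_perm=0)
        proj = ps.eco_project(Y, C, pls, mode="axes")
        assert proj.shape == (n, 4)  # min(p, q) PLS axes
        scores = ps.eco_project(Y, C, pls, mode="scores")
        assert scores.shape == (n, 1)

    def test_unknown_mode(self, rng):
        n = 8
        C = np.eye(n)
        X = rng.normal(size=(n, 2))
        Y = rng.normal(size=(n, 3))
        pls = ps.phylo_pls(X, Y, C, n_perm=0)
        with pytest.raises(ValueError, match="mode"):
            ps.eco_project(Y, C, pls, mode="bogus")
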