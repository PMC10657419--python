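"""ssBSS: DCT basis, SVD features, temporal/spatial alternating fits."""
import numpy as np
import pytest

from swdl._utils import abs_corr_matrix
from swdl.ssbss import (SparseSpatiotemporalBSS, SsbssParams, dct_basis,
                        fit_spatial, fit_temporal, run_ssbss, svd_features)


class TestDctBasis:
    def test_orthonormal(self):
        T = dct_basis(4, 4)
        np.testing.assert_allclose(T.T @ T, np.eye(4), atol=1e-12)

    def test_constant_first_column(self):
        T = dct_basis(9, 3)
        np.testing.assert_allclose(T[:, 0], 1 / 3.0, atol=1e-12)

    def test_sign_change_count(self):
        T = dct_basis(32, 8)
        for j in range(8):
            signs = np.sign(T[:, j])
            changes = int(np.sum(signs[:-1] * signs[1:] < 0))
            assert changes == j

    def test_bounds(self):
        with pytest.raises(ValueError):
            dct_basis(4, 5)


class TestSvdFeatures:
    def test_exact_low_rank(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((20, 5)) @ rng.standard_normal((5, 50))
        X_t, X_s = svd_features(Y, 5)
        assert np.linalg.norm(Y - X_t @ X_s) < 1e-8

    def test_eckart_young_matches_dense_svd(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((20, 50))
        X_t, X_s = svd_features(Y, 5)
        s = np.linalg.svd(Y, compute_uv=False)
        tail = np.sqrt(np.sum(s[5:] ** 2))
        assert abs(np.linalg.norm(Y - X_t @ X_s) - tail) < 1e-10

    def test_orthonormal_left_factor(self):
        rng = np.random.default_rng(2)
        X_t, _ = svd_features(rng.standard_normal((30, 40)), 6)
        np.testing.assert_allclose(X_t.T @ X_t, np.eye(6), atol=1e-10)

    def test_rank_truncation_warns(self):
        Y = np.outer(np.arange(1.0, 11.0), np.arange(1.0, 6.0))
        with pytest.warns(UserWarning, match="rank"):
            X_t, X_s = svd_features(Y, 4)
        assert X_t.shape[1] == 1


def als_temporal_oracle(G, C0, n_sweeps=200):
    """Unconstrained alternating least squares for min ||G - C Q||^2."""
    C = C0.copy()
    Q = np.linalg.lstsq(C, G, rcond=None)[0]
    for _ in range(n_sweeps):
        Q = np.linalg.lstsq(C, G, rcond=None)[0]
        C = np.linalg.lstsq(Q.T, G.T, rcond=None)[0].T
    return float(np.sum((G - C @ Q) ** 2))


class TestFitTemporal:
    def test_planted_model_recovered(self):
        """Band-disjoint planted sparse mixings are recovered exactly."""
        rng = np.random.default_rng(3)
        n, kp, P, K, z1 = 60, 20, 3, 3, 4
        T_p = dct_basis(n, kp)
        C_star = np.zeros((kp, P))
        for p in range(P):
            C_star[p * z1:(p + 1) * z1, p] = 1.0 + rng.random(z1)
        C_star /= np.linalg.norm(C_star, axis=0)
        Q_star = rng.standard_normal((P, K)) + 2 * np.eye(P)
        X_t = T_p @ C_star @ Q_star
        params = SsbssParams(n_components=P, dct_rank=kp, zeta1=z1,
                             lambda1=0.0, iters=500, n_features=K)
        C, Q = fit_temporal(X_t, T_p, params, rng=np.random.default_rng(0))
        obj = float(np.sum((X_t - T_p @ C @ Q) ** 2))
        assert obj <= 1e-6

    def test_constraints_enforced(self):
        rng = np.random.default_rng(4)
        T_p = dct_basis(40, 15)
        X_t = rng.standard_normal((40, 4))
        params = SsbssParams(n_components=4, dct_rank=15, zeta1=5,
                             iters=10, n_features=4)
        C, _ = fit_temporal(X_t, T_p, params, rng=rng)
        assert np.all(np.count_nonzero(C, axis=0) <= 5)
        np.testing.assert_allclose(
            np.linalg.norm(T_p @ C, axis=0), 1.0, atol=1e-8
        )

    def test_full_zeta_matches_unconstrained_als(self):
        """zeta1 = K_p reduces to plain alternating least squares."""
        rng = np.random.default_rng(5)
        n, kp, P = 30, 6, 2
        T_p = dct_basis(n, kp)
        X_t = rng.standard_normal((n, P))
        C0 = np.random.default_rng(7).standard_normal((kp, P))
        C0 /= np.linalg.norm(C0, axis=0)
        params = SsbssParams(n_components=P, dct_rank=kp, zeta1=kp,
                             iters=200, n_features=P)
        C, Q = fit_temporal(X_t, T_p, params, C_init=C0)
        # compare within the DCT span (the component outside it is fixed)
        G = T_p.T @ X_t
        obj = float(np.sum((G - C @ Q) ** 2))
        oracle = als_temporal_oracle(G, C0)
        assert abs(obj - oracle) <= 1e-8


class TestFitSpatial:
    def test_zero_penalty_matches_als(self):
        rng = np.random.default_rng(6)
        X_s = rng.standard_normal((6, 100))
        Z0 = np.random.default_rng(8).standard_normal((6, 3))
        params = SsbssParams(n_components=3, dct_rank=10, zeta1=5,
                             lambda1=0.0, iters=300)
        Z, S = fit_spatial(X_s, params, Z_init=Z0)
        obj = float(np.sum((X_s - Z @ S) ** 2))
        # oracle: unconstrained ALS from the same init
        Zo, So = Z0.copy(), np.zeros((3, 100))
        for _ in range(300):
            So = np.linalg.lstsq(Zo, X_s, rcond=None)[0]
            Zo = np.linalg.lstsq(So.T, X_s.T, rcond=None)[0].T
        oracle = float(np.sum((X_s - Zo @ So) ** 2))
        assert abs(obj - oracle) <= 1e-8

    def test_total_shrinkage(self):
        rng = np.random.default_rng(7)
        X_s = rng.standard_normal((4, 50))
        params = SsbssParams(n_components=2, dct_rank=10, zeta1=5,
                             lambda1=1e6, iters=5)
        _, S = fit_spatial(X_s, params, rng=rng)
        assert np.allclose(S, 0.0)

    def test_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(9)
        X_s = rng.standard_normal((5, 80))
        nnz = []
        for lam in (0.5, 2.0, 8.0, 32.0):
            params = SsbssParams(n_components=3, dct_rank=10, zeta1=5,
                                 lambda1=lam, iters=50)
            _, S = fit_spatial(X_s, params,
                               Z_init=np.random.default_rng(0).standard_normal((5, 3)))
            nnz.append(int(np.count_nonzero(S)))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestRunSsbss:
    def test_planted_sources_recovered(self):
        """Smooth band-limited TCs with sparse maps are recovered (|corr| >= 0.9).

        Temporal identifiability comes from the l0 constraint on the DCT
        mixing (the planted mixings occupy disjoint frequency bands);
        spatial identifiability comes from the l1 map penalty.
        """
        rng = np.random.default_rng(10)
        n, v, P, kp, z1 = 200, 400, 4, 40, 8
        T_p = dct_basis(n, kp)
        C_star = np.zeros((kp, P))
        for p in range(P):
            C_star[p * z1:(p + 1) * z1, p] = 1.0 + 0.5 * rng.random(z1)
        C_star /= np.linalg.norm(C_star, axis=0)
        T_star = T_p @ C_star
        S_star = np.where(rng.random((P, v)) < 0.06,
                          rng.standard_normal((P, v)) + 5.0, 0.0)
        Y = T_star @ S_star
        params = SsbssParams(n_components=P, dct_rank=kp, zeta1=z1,
                             lambda1=3.0, iters=100, n_features=P)
        res = run_ssbss(Y, params, rng=1)
        corr_t = abs_corr_matrix(res.T.T, T_star.T)
        corr_s = abs_corr_matrix(res.S, S_star)
        assert corr_t.max(axis=0).mean() >= 0.9
        assert corr_s.max(axis=0).mean() >= 0.9

    def test_output_shapes(self, default_bases):
        results, _ = default_bases
        for r in results:
            assert r.T.shape == (300, 9)
            assert r.S.shape == (9, 2500)

    def test_objective_nonincreasing(self, default_bases):
        results, _ = default_bases
        for r in results:
            tr = r.objective_trace
            assert np.all(np.diff(tr) <= 1e-6 * np.abs(tr[:-1]) + 1e-9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((50, 80))
        params = SsbssParams(n_components=3, dct_rank=20, zeta1=8, iters=5)
        a = run_ssbss(Y, params, rng=3)
        b = run_ssbss(Y, params, rng=3)
        np.testing.assert_array_equal(a.T, b.T)
        np.testing.assert_array_equal(a.S, b.S)

    def test_model_class_wraps_run(self):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((40, 60))
        params = SsbssParams(n_components=2, dct_rank=10, zeta1=4, iters=3)
        res = SparseSpatiotemporalBSS(Y, params).fit(rng=1)
        assert "ssBSS" in res.summary()
        np.testing.assert_array_equal(res.T, run_ssbss(Y, params, rng=1).T)
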