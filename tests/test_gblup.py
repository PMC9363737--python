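import numpy as np
import pandas as pd
import pytest

from gpbreed.gblup import (
    MultiTraitGBLUP,
    VarianceComponents,
    cross_relationship,
    estimate_variance_components,
    genomic_relationship,
    predict_progeny_gebv,
    solve_mme,
)
from gpbreed.genome_io import GenotypeMatrix
from gpbreed.synthetic_data import SyntheticScenario, generate_founders, generate_phenotypes


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def gls_blup_oracle(W, K, SA, SE):
    """Dense GLS/BLUP solution: mu = (X'V^-1X)^-1 X'V^-1 w, g = G V^-1 (w - X mu)."""
    n, t = W.shape
    V = np.kron(SA, K) + np.kron(SE, np.eye(n))
    X = np.kron(np.eye(t), np.ones((n, 1)))
    w = W.T.ravel()
    Vi = np.linalg.inv(V)
    mu = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ w)
    g = np.kron(SA, K) @ Vi @ (w - X @ mu)
    return mu, g.reshape(t, n).T


def univariate_reml_oracle(y, K):
    """Independent single-trait REML: profile sigma_e out of the eigen-rotated
    restricted likelihood and minimize over the scalar ratio lam = sA/sE."""
    from scipy.optimize import minimize_scalar

    n = len(y)
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0, None)
    yt, a = U.T @ y, U.T @ np.ones(n)

    def neg2ll(log_lam):
        lam = np.exp(log_lam)
        v = lam * d + 1.0
        F = np.sum(a**2 / v)
        mu = np.sum(a * yt / v) / F
        r = yt - a * mu
        s_e = np.sum(r**2 / v) / (n - 1)
        return np.sum(np.log(v)) + np.log(F) + (n - 1) * np.log(s_e)

    res = minimize_scalar(neg2ll, bounds=(-12, 12), method="bounded",
                          options={"xatol": 1e-12})
    lam = np.exp(res.x)
    v = lam * d + 1.0
    F = np.sum(a**2 / v)
    mu = np.sum(a * yt / v) / F
    s_e = np.sum((yt - a * mu) ** 2 / v) / (n - 1)
    return lam * s_e, s_e


def _random_instance(rng, n, t, p=30):
    M = rng.integers(-1, 2, size=(n, p)).astype(float)
    K = M @ M.T / p + 0.05 * np.eye(n)  # keep K invertible for Eq.-form MME
    A = rng.normal(size=(t, t))
    SA = A @ A.T + 0.1 * np.eye(t)
    B = rng.normal(size=(t, t))
    SE = B @ B.T + 0.1 * np.eye(t)
    W = rng.normal(size=(n, t))
    return W, K, SA, SE


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------


class TestRelationship:
    def test_hand_example(self):
        K = genomic_relationship(np.array([[1, -1], [-1, 1]], dtype=float))
        np.testing.assert_allclose(K, [[1, -1], [-1, 1]])

    def test_fully_heterozygous_gives_zero(self):
        assert np.allclose(genomic_relationship(np.zeros((3, 5))), 0.0)

    def test_diagonal_is_homozygous_fraction(self, rng):
        M = rng.integers(-1, 2, size=(6, 20))
        K = genomic_relationship(M)
        hom_frac = (M != 0).mean(axis=1)
        np.testing.assert_allclose(np.diag(K), hom_frac)

    def test_identical_rows_share_diagonal(self, rng):
        M = rng.integers(-1, 2, size=(4, 6)).astype(float)
        M[1] = M[0]
        K = genomic_relationship(M)
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_cross_relationship_of_self_is_k(self, rng):
        M = rng.integers(-1, 2, size=(5, 8)).astype(float)
        np.testing.assert_allclose(cross_relationship(M, M), genomic_relationship(M))

    def test_cross_relationship_matches_brute_force(self, rng):
        Mp = rng.integers(-1, 2, size=(3, 8)).astype(float)
        Mt = rng.integers(-1, 2, size=(5, 8)).astype(float)
        K_pt = cross_relationship(Mp, Mt)
        for i in range(3):
            for j in range(5):
                assert K_pt[i, j] == pytest.approx(np.dot(Mp[i], Mt[j]) / 8)

    def test_marker_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="marker"):
            cross_relationship(rng.normal(size=(2, 5)), rng.normal(size=(2, 6)))


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------


class TestSolveMME:
    @pytest.mark.parametrize("n,t", [(5, 1), (8, 2), (12, 3), (20, 2)])
    def test_matches_gls_oracle(self, n, t):
        rng = np.random.default_rng(100 + n + t)
        for _ in range(5):
            W, K, SA, SE = _random_instance(rng, n, t)
            mu, g = solve_mme(W, K, VarianceComponents(SA, SE))
            mu_o, g_o = gls_blup_oracle(W, K, SA, SE)
            scale = max(1.0, np.abs(g_o).max())
            np.testing.assert_allclose(mu, mu_o, rtol=1e-8, atol=1e-8)
            np.testing.assert_allclose(g, g_o, rtol=1e-8, atol=1e-8 * scale)

    def test_identity_kernel_closed_form(self):
        # t=1, K=I, sA=sE=1: g = (w - wbar)/2 per coordinate (ridge shrinkage)
        w = np.array([1.0, 2.0, 6.0])
        mu, g = solve_mme(w[:, None], np.eye(3), VarianceComponents([[1.0]], [[1.0]]))
        assert mu[0] == pytest.approx(w.mean())
        np.testing.assert_allclose(g[:, 0], (w - w.mean()) / 2, atol=1e-10)

    def test_vanishing_residual_interpolates(self):
        rng = np.random.default_rng(4)
        W, K, SA, _ = _random_instance(rng, 6, 2)
        SE = 1e-10 * np.eye(2)
        mu, g = solve_mme(W, K, VarianceComponents(SA, SE))
        fitted = g + mu[None, :]
        np.testing.assert_allclose(fitted, W, atol=1e-6)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


class TestREML:
    def test_single_trait_matches_univariate_oracle(self):
        rng = np.random.default_rng(7)
        sc = SyntheticScenario(
            n_founders=120, n_chromosomes=2, markers_per_chrom=100,
            sigma_A=[[2.0]], sigma_E=[[1.0]], trait_means=(0.0,), seed=7,
        )
        geno, _, _ = generate_founders(sc, rng)
        phen, _ = generate_phenotypes(geno, sc, rng)
        K = genomic_relationship(geno.codes.astype(float))
        y = phen.values()[:, 0]
        vc = estimate_variance_components(y[:, None], K)
        sA_ref, sE_ref = univariate_reml_oracle(y, K)
        assert vc.sigma_A[0, 0] == pytest.approx(sA_ref, abs=1e-4, rel=1e-4)
        assert vc.sigma_E[0, 0] == pytest.approx(sE_ref, abs=1e-4, rel=1e-4)

    def test_zero_variance_is_degenerate(self):
        W = np.ones((10, 1)) * 3.0
        with pytest.raises(ValueError, match="variance"):
            estimate_variance_components(W, np.eye(10))

    def test_convergence_report_attached(self, fitted_model):
        vc = fitted_model["model"].components_
        assert vc.converged
        assert vc.n_iter > 0
        assert np.isfinite(vc.loglik)

    def test_estimates_symmetric_psd(self, fitted_model):
        for S in (fitted_model["model"].sigma_A_, fitted_model["model"].sigma_E_):
            np.testing.assert_allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() >= -1e-10


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


class TestPredict:
    def test_training_clone_recovers_fitted_value(self, fitted_model, small_dataset):
        model = fitted_model["model"]
        geno = small_dataset["geno"]
        j = 5
        clone = GenotypeMatrix(["clone"], geno.markers, geno.codes[[j], :])
        pred = predict_progeny_gebv(model, clone)
        fitted = model.fitted_values().iloc[j]
        np.testing.assert_allclose(pred.iloc[0].to_numpy(), fitted.to_numpy(), atol=1e-6)

    def test_linear_in_progeny_rows(self, fitted_model, small_dataset):
        model = fitted_model["model"]
        codes = small_dataset["geno"].codes.astype(float)
        mid = (codes[[0]] + codes[[1]]) / 2.0
        pred_mid = model.predict(mid).to_numpy()
        pred_both = model.predict(codes[[0, 1]]).to_numpy()
        # GEBV is affine in the marker row, so mid-parent GEBV = parent average
        np.testing.assert_allclose(pred_mid[0], pred_both.mean(axis=0), atol=1e-8)

    def test_matches_dense_oracle_on_random_instance(self):
        rng = np.random.default_rng(11)
        W, K, SA, SE = _random_instance(rng, 10, 2, p=15)
        M = rng.integers(-1, 2, size=(10, 15)).astype(float)
        K = genomic_relationship(M)
        vc = VarianceComponents(SA, SE)
        model = MultiTraitGBLUP().fit(M, W, components=vc)
        Mp = rng.integers(-1, 2, size=(4, 15)).astype(float)
        pred = model.predict(Mp).to_numpy()
        mu, g = solve_mme(W, K, vc)
        K_inv = np.linalg.inv(K + 1e-6 * np.mean(np.diag(K)) * np.eye(10)) \
            if np.linalg.cond(K) > 1e10 else np.linalg.inv(K)
        expected = Mp @ M.T / 15 @ K_inv @ g + mu[None, :]
        np.testing.assert_allclose(pred, expected, rtol=1e-8, atol=1e-8)

    def test_marker_set_mismatch_errors(self, fitted_model):
        with pytest.raises(ValueError, match="marker"):
            fitted_model["model"].predict(np.zeros((2, 3)))


class TestPersistence:
    def test_save_load_round_trip(self, fitted_model, small_dataset, tmp_path):
        model = fitted_model["model"]
        path = tmp_path / "model.npz"
        model.save(path)
        back = MultiTraitGBLUP.load(path)
        codes = small_dataset["geno"].codes[:3].astype(float)
        np.testing.assert_allclose(
            back.predict(codes).to_numpy(), model.predict(codes).to_numpy()
        )
        pd.testing.assert_series_equal(back.mu_hat_, model.mu_hat_)


def test_sklearn_get_params_round_trip():
    model = MultiTraitGBLUP(max_iter=123)
    params = model.get_params()
    assert params["max_iter"] == 123
    assert MultiTraitGBLUP(**params).max_iter == 123
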