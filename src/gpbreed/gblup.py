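"""Additive multi-trait GBLUP: REML variance components, Henderson's mixed-model
equations, and GEBV prediction for unphenotyped individuals.

Model, for t traits measured on n training individuals with normalized
phenotypes stacked trait-major as w = [w_1; ...; w_t]:

    w = mu (x) 1_n + g + e,   g ~ MVN(0, Sigma_A (x) K),   e ~ MVN(0, Sigma_e (x) I_n)

where (x) is the Kronecker product and K = M M^T / p is the genomic
relationship matrix built from the {-1,0,1} marker coding matrix M.

Sigma_A and Sigma_e are estimated by REML. After the eigendecomposition
K = U diag(d) U^T, rotating each trait vector by U^T decouples the
restricted likelihood into n independent t-variate Gaussian terms with
covariance d_j*Sigma_A + Sigma_e, which makes direct quasi-Newton
maximization over Cholesky-parameterized (Sigma_A, Sigma_e) cheap and
stable for the small t used in breeding programs.

BLUE/BLUP (mu_hat, g_hat) solve the mixed-model equations

    [ n I_t            I_t (x) 1_n^T                      ] [mu_hat]   [(I_t (x) 1_n^T) w]
    [ I_t (x) 1_n      I_nt + (Sigma_e Sigma_A^-1)(x)K^-1 ] [g_hat ] = [        w        ]

and genomic values of a progeny population with coding matrix M_p are
predicted per trait as h_i = K_pt K^-1 g_hat_i with K_pt = M_p M^T / p,
giving GEBVs mu_hat_i + h_i on the normalized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .genome_io import GenotypeMatrix

logger = logging.getLogger(__name__)


class REMLError(RuntimeError):
    """REML failed to converge; message carries the optimizer trace."""


@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates of the t x t genetic (Sigma_A) and residual (Sigma_e) covariances."""

    sigma_A: np.ndarray
    sigma_E: np.ndarray
    n_iter: int = 0
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        for name, S in (("sigma_A", self.sigma_A), ("sigma_E", self.sigma_E)):
            S = np.atleast_2d(np.asarray(S, dtype=float))
            if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-8):
                raise ValueError(f"{name} must be a symmetric square matrix")
            object.__setattr__(self, name, (S + S.T) / 2.0)
        if self.sigma_A.shape != self.sigma_E.shape:
            raise ValueError("sigma_A and sigma_E must have the same shape")

    @property
    def t(self) -> int:
        return self.sigma_A.shape[0]


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------


def _codes(M) -> np.ndarray:
    if isinstance(M, GenotypeMatrix):
        return M.codes.astype(float)
    arr = np.asarray(M, dtype=float)
    if arr.ndim != 2:
        raise ValueError("marker matrix must be 2-dimensional")
    return arr


def genomic_relationship(M) -> np.ndarray:
    """K = M M^T / p. With codes in {-1,0,1}, diag(K)_i = (#homozygous loci of i)/p."""
    A = _codes(M)
    if A.shape[1] < 1:
        raise ValueError("need at least one marker")
    return A @ A.T / A.shape[1]


def cross_relationship(M_progeny, M_train) -> np.ndarray:
    """K_pt = M_p M_t^T / p between a progeny set and the training set (shared markers)."""
    if isinstance(M_progeny, GenotypeMatrix) and isinstance(M_train, GenotypeMatrix):
        if M_progeny.markers != M_train.markers:
            raise ValueError("progeny and training genotype matrices use different marker sets")
    A, B = _codes(M_progeny), _codes(M_train)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"marker count mismatch: {A.shape[1]} vs {B.shape[1]}")
    return A @ B.T / A.shape[1]


def nearest_psd(S: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix by eigenvalue clipping."""
    S = (S + S.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    floor = floor_frac * max(np.trace(S), floor_frac)
    if vals.min() >= floor:
        return S
    logger.warning("projecting non-PSD covariance update to nearest PSD (min eig %.3e)", vals.min())
    return (vecs * np.clip(vals, floor, None)) @ vecs.T


def regularized_inverse(K: np.ndarray, cond_threshold: float = 1e10) -> tuple[np.ndarray, bool]:
    """Invert K, adding a ridge 1e-6 * mean(diag K) when ill-conditioned.

    Returns (K_inv, ridged).
    """
    K = (K + K.T) / 2.0
    vals = np.linalg.eigvalsh(K)
    ridged = vals.min() <= 0 or vals.max() / max(vals.min(), np.finfo(float).tiny) > cond_threshold
    if ridged:
        eps = 1e-6 * float(np.mean(np.diag(K)))
        if eps <= 0:
            eps = 1e-6
        logger.info("K ill-conditioned (eigen range %.3e..%.3e); adding ridge %.3e", vals.min(), vals.max(), eps)
        K = K + eps * np.eye(K.shape[0])
    return np.linalg.inv(K), ridged


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _chol_from_theta(theta: np.ndarray, t: int) -> np.ndarray:
    L = np.zeros((t, t))
    idx = 0
    for i in range(t):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L


def _theta_from_cov(S: np.ndarray) -> np.ndarray:
    t = S.shape[0]
    L = np.linalg.cholesky(S + 1e-10 * np.trace(S) * np.eye(t))
    out = []
    for i in range(t):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def _neg2_restricted_ll(d: np.ndarray, a: np.ndarray, Wt: np.ndarray, SA: np.ndarray, SE: np.ndarray) -> float:
    """-2 * restricted log-likelihood (up to a constant) in the eigenbasis of K."""
    V = d[:, None, None] * SA[None, :, :] + SE[None, :, :]  # (n, t, t)
    sign, logdet = np.linalg.slogdet(V)
    if np.any(sign <= 0):
        return np.inf
    Vinv = np.linalg.inv(V)
    F = np.einsum("j,jab->ab", a**2, Vinv)
    b = np.einsum("j,jab,jb->a", a, Vinv, Wt)
    signF, logdetF = np.linalg.slogdet(F)
    if signF <= 0:
        return np.inf
    mu = np.linalg.solve(F, b)
    quad = float(np.einsum("ja,jab,jb->", Wt, Vinv, Wt) - mu @ F @ mu)
    return float(logdet.sum() + logdetF + quad)


def estimate_variance_components(
    W,
    K: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> VarianceComponents:
    """REML estimates of (Sigma_A, Sigma_e) for the multi-trait GBLUP model.

    Parameters
    ----------
    W : array-like (n, t)
        Normalized phenotypes, one column per trait.
    K : (n, n) genomic relationship matrix (PSD).
    max_iter : optimizer iteration cap.
    tol : relative tolerance on the restricted log-likelihood.

    Raises
    ------
    REMLError if the optimizer does not converge, with the trace attached.
    ValueError for degenerate (zero-variance) phenotypes.
    """
    W = np.asarray(W.to_numpy() if isinstance(W, pd.DataFrame) else W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    n, t = W.shape
    if n <= t:
        raise ValueError(f"need more individuals than traits (n={n}, t={t})")
    S = np.cov(W, rowvar=False, ddof=1).reshape(t, t)
    if np.any(np.diag(S) < 1e-12):
        raise ValueError("a trait has (near-)zero phenotypic variance; REML is degenerate")

    d, U = np.linalg.eigh((K + K.T) / 2.0)
    d = np.clip(d, 0.0, None)
    Wt = U.T @ W  # (n, t)
    a = U.T @ np.ones(n)

    k = t * (t + 1) // 2

    def objective(theta: np.ndarray) -> float:
        LA = _chol_from_theta(theta[:k], t)
        LE = _chol_from_theta(theta[k:], t)
        return _neg2_restricted_ll(d, a, Wt, LA @ LA.T, LE @ LE.T)

    x0 = np.concatenate([_theta_from_cov(S / 2.0), _theta_from_cov(S / 2.0)])
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not res.success and res.status != 1:  # status 1 = hit maxiter
        raise REMLError(f"REML did not converge: {res.message} (nit={res.nit}, fun={res.fun:.6g})")
    if not res.success:
        raise REMLError(f"REML hit the iteration cap ({max_iter}): {res.message}")
    LA = _chol_from_theta(res.x[:k], t)
    LE = _chol_from_theta(res.x[k:], t)
    return VarianceComponents(
        sigma_A=LA @ LA.T,
        sigma_E=LE @ LE.T,
        n_iter=int(res.nit),
        loglik=-0.5 * float(res.fun),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------


def solve_mme(
    W,
    K: np.ndarray,
    components: VarianceComponents,
    cond_threshold: float = 1e10,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the mixed-model equations for (mu_hat, g_hat).

    The system is assembled exactly in the Sigma_e-premultiplied block form
    (see module docstring), with trait-major stacking. Returns mu_hat of
    shape (t,) and g_hat of shape (n, t).
    """
    W = np.asarray(W.to_numpy() if isinstance(W, pd.DataFrame) else W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    n, t = W.shape
    if components.t != t:
        raise ValueError(f"components are for t={components.t} traits, data has t={t}")
    SA = nearest_psd(components.sigma_A)
    SE = (components.sigma_E + components.sigma_E.T) / 2.0
    SA_inv = np.linalg.inv(SA)
    K_inv, _ = regularized_inverse(K, cond_threshold)

    w = W.T.ravel()  # trait-major: [w_1; ...; w_t]
    I_t = np.eye(t)
    ones_row = np.ones((1, n))
    top = np.hstack([n * I_t, np.kron(I_t, ones_row)])
    bottom = np.hstack([np.kron(I_t, ones_row.T), np.eye(n * t) + np.kron(SE @ SA_inv, K_inv)])
    A = np.vstack([top, bottom])
    rhs = np.concatenate([np.kron(I_t, ones_row) @ w, w])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"mixed-model equations singular after regularization: {exc}") from exc
    mu_hat = sol[:t]
    g_hat = sol[t:].reshape(t, n).T
    return mu_hat, g_hat


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class MultiTraitGBLUP(BaseEstimator):
    """Multi-trait GBLUP estimator with an sklearn-style fit/predict surface.

    ``fit(M, W)`` takes the coded marker matrix M (n x p, entries -1/0/1) and
    normalized phenotypes W (n x t); it computes K = M M^T / p, REML estimates
    of (Sigma_A, Sigma_e), and the BLUE/BLUP solution of the mixed-model
    equations. ``predict(M_new)`` returns normalized-scale GEBVs
    mu_hat_i + K_pt K^-1 g_hat_i for new individuals genotyped on the same
    markers. Variance components are estimated once at fit time and reused
    for every downstream prediction.

    Parameters
    ----------
    max_iter : REML iteration cap.
    tol : REML convergence tolerance (relative log-likelihood change).
    cond_threshold : condition-number threshold above which K receives a
        diagonal ridge of 1e-6 * mean(diag K) before inversion.

    Attributes
    ----------
    K_ : (n, n) genomic relationship matrix of the training set.
    K_inv_ : its (possibly ridged) inverse.
    mu_hat_ : pd.Series, BLUE of the trait means (normalized scale).
    g_hat_ : pd.DataFrame (n x t), BLUP genomic values of training individuals.
    sigma_A_, sigma_E_ : REML variance-component estimates.
    components_ : VarianceComponents (with convergence report).
    ridged_ : whether K required regularization.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-9, cond_threshold: float = 1e10):
        self.max_iter = max_iter
        self.tol = tol
        self.cond_threshold = cond_threshold

    def fit(self, M, W, components: VarianceComponents | None = None) -> "MultiTraitGBLUP":
        """Fit on training markers M and normalized phenotypes W.

        Supplying ``components`` skips REML and solves the MME with the
        given variance components.
        """
        if isinstance(M, GenotypeMatrix):
            self.marker_ids_ = list(M.markers)
            self.train_ids_ = list(M.accessions)
        else:
            self.marker_ids_ = None
            self.train_ids_ = None
        codes = _codes(M)
        if isinstance(W, pd.DataFrame):
            self.trait_names_ = list(W.columns)
            if self.train_ids_ is None:
                self.train_ids_ = list(W.index.astype(str))
            Wv = W.to_numpy(dtype=float)
        else:
            Wv = np.asarray(W, dtype=float)
            if Wv.ndim == 1:
                Wv = Wv[:, None]
            self.trait_names_ = [f"trait{i}" for i in range(Wv.shape[1])]
        if codes.shape[0] != Wv.shape[0]:
            raise ValueError("genotypes and phenotypes disagree on the number of individuals")
        if self.train_ids_ is None:
            self.train_ids_ = [f"ind{i}" for i in range(codes.shape[0])]

        self.M_train_ = codes
        self.K_ = genomic_relationship(codes)
        if components is None:
            components = estimate_variance_components(Wv, self.K_, max_iter=self.max_iter, tol=self.tol)
        self.components_ = components
        self.sigma_A_ = components.sigma_A
        self.sigma_E_ = components.sigma_E
        mu, g = solve_mme(Wv, self.K_, components, cond_threshold=self.cond_threshold)
        self.K_inv_, self.ridged_ = regularized_inverse(self.K_, self.cond_threshold)
        self.mu_hat_ = pd.Series(mu, index=self.trait_names_)
        self.g_hat_ = pd.DataFrame(g, index=self.train_ids_, columns=self.trait_names_)
        self.n_features_in_ = codes.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "g_hat_"):
            raise ValueError("MultiTraitGBLUP instance is not fitted")

    def fitted_values(self) -> pd.DataFrame:
        """Training-set GEBVs mu_hat + g_hat on the normalized scale."""
        self._check_fitted()
        return self.g_hat_ + self.mu_hat_

    def predict(self, M_new, ids=None) -> pd.DataFrame:
        """Normalized-scale GEBVs for new individuals on the training markers."""
        self._check_fitted()
        if isinstance(M_new, GenotypeMatrix):
            if self.marker_ids_ is not None and M_new.markers != self.marker_ids_:
                raise ValueError("prediction genotypes use a different marker set than training")
            if ids is None:
                ids = M_new.accessions
        codes = _codes(M_new)
        if codes.shape[1] != self.M_train_.shape[1]:
            raise ValueError(f"marker count mismatch: {codes.shape[1]} vs {self.M_train_.shape[1]}")
        K_pt = codes @ self.M_train_.T / codes.shape[1]
        H = K_pt @ self.K_inv_ @ self.g_hat_.to_numpy()
        gebv = H + self.mu_hat_.to_numpy()[None, :]
        if ids is None:
            ids = [f"pred{i}" for i in range(codes.shape[0])]
        return pd.DataFrame(gebv, index=ids, columns=self.trait_names_)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted model (matrices + metadata) to a single .npz archive."""
        self._check_fitted()
        np.savez_compressed(
            path,
            M_train=self.M_train_,
            K=self.K_,
            K_inv=self.K_inv_,
            mu_hat=self.mu_hat_.to_numpy(),
            g_hat=self.g_hat_.to_numpy(),
            sigma_A=self.sigma_A_,
            sigma_E=self.sigma_E_,
            trait_names=np.array(self.trait_names_, dtype=object),
            train_ids=np.array(self.train_ids_, dtype=object),
            marker_ids=np.array(self.marker_ids_ if self.marker_ids_ is not None else [], dtype=object),
            ridged=np.array([self.ridged_]),
        )

    @classmethod
    def load(cls, path) -> "MultiTraitGBLUP":
        data = np.load(path, allow_pickle=True)
        model = cls()
        model.M_train_ = data["M_train"]
        model.K_ = data["K"]
        model.K_inv_ = data["K_inv"]
        model.trait_names_ = list(data["trait_names"])
        model.train_ids_ = list(data["train_ids"])
        marker_ids = list(data["marker_ids"])
        model.marker_ids_ = marker_ids if marker_ids else None
        model.sigma_A_ = data["sigma_A"]
        model.sigma_E_ = data["sigma_E"]
        model.components_ = VarianceComponents(data["sigma_A"], data["sigma_E"])
        model.mu_hat_ = pd.Series(data["mu_hat"], index=model.trait_names_)
        model.g_hat_ = pd.DataFrame(data["g_hat"], index=model.train_ids_, columns=model.trait_names_)
        model.ridged_ = bool(data["ridged"][0])
        model.n_features_in_ = model.M_train_.shape[1]
        return model


def predict_progeny_gebv(model: MultiTraitGBLUP, M_progeny, ids=None) -> pd.DataFrame:
    """GEBVs (normalized scale) of a progeny population under a fitted model."""
    return model.predict(M_progeny, ids=ids)
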