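"""Sparse spatiotemporal blind source separation (ssBSS).

Decomposes one subject's data matrix Y (N scans x V voxels) into P temporal
sources T = T_p C and P spatial sources S:

    min ||Y - T_p C S||_F^2 + lambda1 ||S||_1
    s.t. ||T_p c_p||_2 = 1,  ||c_p||_0 <= zeta1

where T_p holds the first K_p orthonormal DCT-II bases (BOLD smoothness
prior).  The problem is split via a rank-K SVD of Y into decoupled temporal
and spatial subproblems on the feature matrices X_t (N x K) and X_s (K x V):

    min ||X_t - T_p C Q||_F^2          (unit-norm, l0-sparse columns of C)
    min ||X_s - Z S||_F^2 + lambda1 ||S||_1

both solved by alternating least squares with l0 projection (temporal) and
coordinate-wise soft thresholding (spatial).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import idct

from ._utils import ridge_solve, top_k_support
from .preprocess import SubjectMatrix

__all__ = [
    "SsbssParams",
    "SsbssResult",
    "SparseSpatiotemporalBSS",
    "dct_basis",
    "svd_features",
    "fit_temporal",
    "fit_spatial",
    "run_ssbss",
]

_EPS_DENOM = 1e-12
_RIDGE = 1e-8


def dct_basis(n: int, k: int) -> np.ndarray:
    """Orthonormal DCT-II basis: n x k, lowest k frequencies, constant first."""
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    eye = np.eye(n)[:, :k]
    return idct(eye, axis=0, norm="ortho")


def svd_features(Y: SubjectMatrix | np.ndarray, K: int):
    """Rank-K SVD feature extraction.

    Returns ``X_t`` (N x K, orthonormal left singular vectors) and ``X_s``
    (K x V, singular values times right singular vectors), so that
    ``X_t @ X_s`` is the best rank-K approximation of Y.
    """
    A = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
    if K > min(A.shape):
        raise ValueError("K exceeds min(N, V)")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps)) if s.size else 0
    if K > rank:
        warnings.warn(f"K={K} exceeds numerical rank {rank}; truncating", stacklevel=2)
        K = max(rank, 1)
    X_t = U[:, :K]
    X_s = s[:K, None] * Vt[:K]
    return X_t, X_s


@dataclass(frozen=True)
class SsbssParams:
    """Tuning parameters of the ssBSS decomposition."""

    n_components: int = 9  # P
    dct_rank: int = 150  # K_p
    zeta1: int = 30  # max nonzeros per column of C
    lambda1: float = 6.0  # spatial l1 weight
    iters: int = 15
    n_features: int | None = None  # K; defaults to P

    def __post_init__(self) -> None:
        if self.zeta1 < 1:
            raise ValueError("zeta1 must be >= 1")
        if self.zeta1 > self.dct_rank:
            raise ValueError("zeta1 cannot exceed dct_rank")
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if self.n_components >= self.dct_rank:
            warnings.warn(
                "expected n_components < dct_rank; results may be degenerate",
                stacklevel=2,
            )

    @property
    def K(self) -> int:
        return self.n_features if self.n_features is not None else self.n_components


def _temporal_sweep(G, C, Q, zeta1):
    """One alternating sweep of min ||G - C Q||^2 over (Q, sparse C).

    G = T_p^T X_t.  Q is solved by ridge least squares; each column of C is
    the entrywise-exact l0-projected rank-1 least squares update (top-zeta1
    magnitudes of the unconstrained coefficients), then rescaled to unit
    norm with the inverse scale absorbed into Q so the fit is unchanged.
    """
    Q = ridge_solve(C.T @ C, C.T @ G, _RIDGE)
    P = C.shape[1]
    R = G - C @ Q
    for p in range(P):
        q = Q[p]
        denom = float(q @ q)
        if denom < _EPS_DENOM:
            continue
        Rp = R + np.outer(C[:, p], q)
        coef = Rp @ q / denom
        supp = top_k_support(coef, zeta1)
        c_new = np.zeros_like(coef)
        c_new[supp] = coef[supp]
        nu = float(np.linalg.norm(c_new))
        if nu < _EPS_DENOM:
            continue
        C[:, p] = c_new / nu
        Q[p] = nu * q
        R = Rp - np.outer(C[:, p], Q[p])
    return C, Q


def fit_temporal(X_t, T_p, params: SsbssParams, rng=None, n_sweeps=None,
                 C_init=None):
    """Fit the temporal subproblem; returns (C, Q).

    ``T_p`` must have orthonormal columns (DCT-II basis).  Initial C is
    standard normal with unit-norm columns unless supplied.
    """
    if params.zeta1 < 1:
        raise ValueError("zeta1 must be >= 1")
    X_t = np.asarray(X_t, dtype=float)
    G = T_p.T @ X_t
    Kp, P = T_p.shape[1], params.n_components
    if C_init is None:
        rng = np.random.default_rng() if rng is None else rng
        C = rng.standard_normal((Kp, P))
        C /= np.linalg.norm(C, axis=0, keepdims=True)
    else:
        C = np.array(C_init, dtype=float)
    Q = ridge_solve(C.T @ C, C.T @ G, _RIDGE)
    sweeps = params.iters if n_sweeps is None else n_sweeps
    for _ in range(sweeps):
        C, Q = _temporal_sweep(G, C, Q, params.zeta1)
    return C, Q


def _spatial_sweep(X_s, Z, S, lam1):
    """One sweep: coordinate-wise soft-thresholded rows of S, then LS for Z."""
    P = Z.shape[1]
    R = X_s - Z @ S
    for k in range(P):
        z = Z[:, k]
        denom = float(z @ z)
        if denom < _EPS_DENOM:
            continue
        Rk = R + np.outer(z, S[k])
        u = z @ Rk
        S[k] = np.sign(u) * np.maximum(np.abs(u) - 0.5 * lam1, 0.0) / denom
        R = Rk - np.outer(z, S[k])
    Z = ridge_solve(S @ S.T, S @ X_s.T, _RIDGE).T
    return Z, S


def fit_spatial(X_s, params: SsbssParams, rng=None, n_sweeps=None, Z_init=None):
    """Fit the spatial subproblem; returns (Z, S)."""
    X_s = np.asarray(X_s, dtype=float)
    K, V = X_s.shape
    P = params.n_components
    if Z_init is None:
        rng = np.random.default_rng() if rng is None else rng
        Z = rng.standard_normal((K, P))
    else:
        Z = np.array(Z_init, dtype=float)
    S = np.zeros((P, V))
    sweeps = params.iters if n_sweeps is None else n_sweeps
    for _ in range(sweeps):
        Z, S = _spatial_sweep(X_s, Z, S, params.lambda1)
    return Z, S


@dataclass
class SsbssResult:
    """Fitted ssBSS decomposition of one subject."""

    T_p: np.ndarray  # N x K_p DCT basis
    C: np.ndarray  # K_p x P sparse mixing
    Q: np.ndarray  # P x K temporal loadings
    Z: np.ndarray  # K x P spatial loadings
    S: np.ndarray  # P x V spatial sources
    X_t: np.ndarray  # N x K temporal features
    X_s: np.ndarray  # K x V spatial features
    params: SsbssParams
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    constraint_trace: list = field(default_factory=list)

    @property
    def T(self) -> np.ndarray:
        """Temporal sources T = T_p C (N x P, unit-norm columns)."""
        return self.T_p @ self.C

    def summary(self) -> str:
        P = self.params.n_components
        lines = [
            "ssBSS decomposition",
            "-" * 40,
            f"components (P):        {P}",
            f"DCT rank (K_p):        {self.T_p.shape[1]}",
            f"zeta1 / lambda1:       {self.params.zeta1} / {self.params.lambda1}",
            f"sweeps:                {len(self.objective_trace)}",
            f"final objective:       {self.objective_trace[-1]:.6g}"
            if self.objective_trace.size
            else "final objective:       n/a",
            f"S sparsity (frac 0):   {float(np.mean(self.S == 0)):.3f}",
            f"max |1 - ||T_p c_p||2|: {float(np.max(np.abs(np.linalg.norm(self.C, axis=0) - 1))):.2e}",
        ]
        return "\n".join(lines)


class SparseSpatiotemporalBSS:
    """ssBSS model for one subject's scans x voxels matrix.

    Parameters mirror :class:`SsbssParams`; ``fit`` runs the SVD feature
    extraction followed by alternating temporal/spatial sweeps and returns
    an :class:`SsbssResult`.
    """

    def __init__(self, Y: SubjectMatrix | np.ndarray, params: SsbssParams | None = None,
                 **kwargs):
        self.Y = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
        self.params = params if params is not None else SsbssParams(**kwargs)

    def fit(self, rng: np.random.Generator | int | None = None) -> SsbssResult:
        return run_ssbss(self.Y, self.params, rng)


def run_ssbss(Y, params: SsbssParams, rng=None) -> SsbssResult:
    """Run the full ssBSS pipeline on one subject.

    Records the combined objective
    ||X_t - T_p C Q||^2 + ||X_s - Z S||^2 + lambda1*||S||_1 after every
    sweep (block coordinate descent, hence nonincreasing), plus constraint
    diagnostics (unit-norm deviation and nnz of the columns of C).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    A = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
    N = A.shape[0]
    X_t, X_s = svd_features(A, params.K)
    K = X_t.shape[1]
    T_p = dct_basis(N, params.dct_rank)
    G = T_p.T @ X_t
    const_t = float(np.sum(X_t**2) - np.sum(G**2))  # energy outside span(T_p)

    Kp, P, V = params.dct_rank, params.n_components, X_s.shape[1]
    C = rng.standard_normal((Kp, P))
    C /= np.linalg.norm(C, axis=0, keepdims=True)
    Q = ridge_solve(C.T @ C, C.T @ G, _RIDGE)
    Z = rng.standard_normal((K, P))
    S = np.zeros((P, V))

    trace = []
    cons = []
    for _ in range(params.iters):
        C, Q = _temporal_sweep(G, C, Q, params.zeta1)
        Z, S = _spatial_sweep(X_s, Z, S, params.lambda1)
        obj = (
            const_t
            + float(np.sum((G - C @ Q) ** 2))
            + float(np.sum((X_s - Z @ S) ** 2))
            + params.lambda1 * float(np.sum(np.abs(S)))
        )
        trace.append(obj)
        cons.append(
            {
                "unit_norm_dev": float(np.max(np.abs(np.linalg.norm(C, axis=0) - 1.0))),
                "max_nnz_c": int(np.max(np.count_nonzero(C, axis=0))),
            }
        )
    return SsbssResult(
        T_p=T_p, C=C, Q=Q, Z=Z, S=S, X_t=X_t, X_s=X_s, params=params,
        objective_trace=np.asarray(trace), constraint_trace=cons,
    )
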