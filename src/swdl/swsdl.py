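"""Subject-wise sequential dictionary learning (swsDL).

Sequential rank-1 refinement of the representation pair (A_m, B_m) over
the multi-subject bases (D_q, X_q).  For atom k with error matrix
E_k = Y - sum_{i != k} d_i x^i:

* code row: adaptive soft threshold of xi = d_k^T E_k
  (per-entry penalty lambda2 / (2 |xi_j|)),
* b_m^k: l0-restricted least squares of the thresholded row onto the rows
  of X_q (support = zeta3 largest |correlations|),
* atom direction d* = d_k + E_k x^T / (x x^T), computed on the support of
  the current code row,
* a_{m,k}: l0-restricted least squares of d* onto the columns of D_q
  (support = zeta2 largest |projections|), rescaled to ||D_q a||_2 = 1.
"""
from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from ._utils import adaptive_soft_threshold, top_k_support
from .preprocess import SubjectMatrix
from .swbdl import SWModel, fit_b

logger = logging.getLogger(__name__)

__all__ = [
    "SwsdlParams",
    "SubjectwiseSequentialDL",
    "error_matrix",
    "adaptive_code_row",
    "restricted_b",
    "restricted_a",
    "run_swsdl",
]

_EPS = 1e-12


@dataclass(frozen=True)
class SwsdlParams:
    """swsDL tuning parameters."""

    lambda2: float = 16.0
    zeta2: int = 24  # max nonzeros of a_{m,k}
    zeta3: int = 24  # max nonzeros of b_m^k
    iters: int = 15

    def __post_init__(self) -> None:
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be >= 0")
        if self.zeta2 < 1 or self.zeta3 < 1:
            raise ValueError("zeta2 and zeta3 must be >= 1")


def error_matrix(Y: np.ndarray, D: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    """E_k = Y - sum_{i != k} d_i x^i (direct computation)."""
    K = D.shape[1]
    if not 0 <= k < K:
        raise ValueError("k out of range")
    return Y - D @ X + np.outer(D[:, k], X[k])


def adaptive_code_row(xi: np.ndarray, lam2: float) -> np.ndarray:
    """Adaptive threshold sgn(xi)*(|xi| - lam2/(2|xi|))_+ with tiny-entry guard."""
    return adaptive_soft_threshold(xi, lam2)


def restricted_b(x_row: np.ndarray, X_q: np.ndarray, zeta3: int) -> np.ndarray:
    """l0-restricted least squares of a code row onto the rows of X_q.

    Support = indices of the zeta3 largest normalised correlation scores
    |x_row . g_i| / ||g_i|| over the rows g_i of X_q (optimal for a single
    row and for mutually orthogonal rows); on the support b solves
    min ||x_row - b X_q||_2^2, off-support entries are zero.
    """
    if zeta3 < 1:
        raise ValueError("zeta3 must be >= 1")
    # normalised correlation scores: optimal single-row selection, and
    # equal to plain inner products when the rows have equal norm
    norms = np.linalg.norm(X_q, axis=1)
    scores = (X_q @ x_row) / np.where(norms == 0, 1.0, norms)
    supp = top_k_support(scores, zeta3)
    b_s = np.linalg.lstsq(X_q[supp].T, x_row, rcond=None)[0]
    b = np.zeros(X_q.shape[0])
    b[supp] = b_s
    return b


def restricted_a(D_q: np.ndarray, d_star: np.ndarray, zeta2: int) -> np.ndarray:
    """l0-restricted least squares of d* onto the columns of D_q.

    Support = indices of the zeta2 largest normalised correlation scores
    |d* . c_i| / ||c_i|| over the columns c_i of D_q; the restricted
    solution is rescaled so that ||D_q a||_2 = 1.
    """
    if zeta2 < 1:
        raise ValueError("zeta2 must be >= 1")
    if not np.all(np.isfinite(d_star)):
        raise ValueError("d_star must be finite")
    norms = np.linalg.norm(D_q, axis=0)
    scores = (D_q.T @ d_star) / np.where(norms == 0, 1.0, norms)
    supp = top_k_support(scores, zeta2)
    a_s = np.linalg.lstsq(D_q[:, supp], d_star, rcond=None)[0]
    a = np.zeros(D_q.shape[1])
    a[supp] = a_s
    norm = np.linalg.norm(D_q @ a)
    if norm < _EPS:
        raise ValueError("restricted projection collapsed to zero")
    return a / norm


def _objective(Y, D, X, lam2):
    return float(np.sum((Y - D @ X) ** 2)) + lam2 * float(np.sum(np.abs(X)))


class SubjectwiseSequentialDL:
    """swsDL model for one subject over multi-subject bases (D_q, X_q).

    ``fit`` runs the sequential sweeps and returns an :class:`SWModel`
    whose dictionary / code are D_q A and B X_q.
    """

    def __init__(self, Y: SubjectMatrix | np.ndarray, D_q: np.ndarray,
                 X_q: np.ndarray, n_atoms: int = 9,
                 params: SwsdlParams | None = None,
                 A_init: np.ndarray | None = None,
                 B_init: np.ndarray | None = None, **kwargs):
        self.Y = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
        self.D_q = np.asarray(D_q, dtype=float)
        self.X_q = np.asarray(X_q, dtype=float)
        if self.D_q.shape[1] != self.X_q.shape[0]:
            raise ValueError("D_q columns must match X_q rows")
        if n_atoms > self.Y.shape[0]:
            raise ValueError("n_atoms must not exceed the number of scans")
        self.n_atoms = n_atoms
        self.params = params if params is not None else SwsdlParams(**kwargs)
        self.A_init = A_init
        self.B_init = B_init

    def fit(self) -> SWModel:
        return run_swsdl(self.Y, self.D_q, self.X_q, self.params,
                         A_init=self.A_init, B_init=self.B_init,
                         n_atoms=self.n_atoms)


def run_swsdl(Y, D_q, X_q, params: SwsdlParams,
              A_init: np.ndarray | None = None,
              B_init: np.ndarray | None = None,
              n_atoms: int | None = None) -> SWModel:
    """Run swsDL sequential sweeps; returns an :class:`SWModel`.

    Initialisation: A from projecting the DCT-initialised dictionary onto
    the base (unless given), B from the initial thresholded code (unless
    given).  The residual R = Y - D X is maintained incrementally and
    E_k = R + d_k x^k.
    """
    from .ssbss import dct_basis
    from .swbdl import block_code_update

    A_data = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
    N = A_data.shape[0]
    MP = D_q.shape[1]
    if A_init is None:
        if n_atoms is None:
            raise ValueError("need n_atoms or A_init")
        # project each DCT-initialised atom onto the base, honouring the
        # zeta2 support constraint from the start; atoms with no base
        # representation fall back to the same-index base column
        D0 = dct_basis(N, n_atoms)
        cols = []
        for k in range(n_atoms):
            try:
                cols.append(restricted_a(D_q, D0[:, k], params.zeta2))
            except ValueError:
                logger.info("init atom %d has no base representation; "
                            "using base column", k)
                a = np.zeros(MP)
                a[k % MP] = 1.0
                cols.append(a / np.linalg.norm(D_q @ a))
        A = np.column_stack(cols)
    else:
        A = np.array(A_init, dtype=float)
    K = A.shape[1]
    D = D_q @ A
    if B_init is None:
        B = fit_b(block_code_update(A_data, D, params.lambda2), X_q)
    else:
        B = np.array(B_init, dtype=float)
    X = B @ X_q
    R = A_data - D @ X
    trace = []
    cons = []
    for _ in range(params.iters):
        for k in range(K):
            E_k = R + np.outer(D[:, k], X[k])
            xi = D[:, k] @ E_k
            x_thr = adaptive_code_row(xi, params.lambda2)
            b_k = restricted_b(x_thr, X_q, params.zeta3)
            x_new = b_k @ X_q
            eps_supp = np.flatnonzero(x_new)
            xx = float(x_new[eps_supp] @ x_new[eps_supp])
            if xx < _EPS:
                logger.debug("dead atom %d: code row vanished, update skipped", k)
                B[k] = b_k
                X[k] = x_new
                R = E_k - np.outer(D[:, k], X[k])
                continue
            d_star = D[:, k] + (E_k[:, eps_supp] @ x_new[eps_supp]) / xx
            a_k = restricted_a(D_q, d_star, params.zeta2)
            A[:, k] = a_k
            D[:, k] = D_q @ a_k
            B[k] = b_k
            X[k] = x_new
            R = E_k - np.outer(D[:, k], X[k])
        trace.append(_objective(A_data, D, X, params.lambda2))
        cons.append(
            {
                "unit_norm_dev": float(np.max(np.abs(np.linalg.norm(D, axis=0) - 1.0))),
                "max_nnz_a": int(np.max(np.count_nonzero(A, axis=0))),
                "max_nnz_b": int(np.max(np.count_nonzero(B, axis=1))),
            }
        )
    return SWModel(A=A, B=B, D_q=D_q, X_q=X_q,
                   objective_trace=np.asarray(trace), constraint_trace=cons,
                   algorithm="swsdl")
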