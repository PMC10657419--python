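"""Subject-wise block dictionary learning (swbDL).

Learns representation matrices A_m (MP x K) and B_m (K x MP) so that the
subject dictionary D_m = D_q A_m and code X_m = B_m X_q approximate the
subject's data through the multi-subject bases (D_q, X_q):

    min ||Y_m - D_q A_m B_m X_q||_F^2
        + alpha ||D_m D_m^T - D_0 D_0^T||_F^2 + lambda2 ||B_m X_q||_1
    s.t. ||D_q a_k||_2 = 1

where D_0 is the lag-1 delayed dictionary; penalising the difference of
the two autocorrelation structures encourages temporally smooth atoms.
Each outer iteration performs: plain soft-threshold code update, least
squares for B_m, an ADMM solve for D_m with the autocorrelation penalty
(relaxation variable U, multiplier W), and a projection back to A_m.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from ._utils import ridge_solve, soft_threshold
from .preprocess import SubjectMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SwbdlParams",
    "AdmmState",
    "SWModel",
    "SubjectwiseBlockDL",
    "lag_dictionary",
    "block_code_update",
    "fit_b",
    "admm_dictionary",
    "project_a",
    "run_swbdl",
]

_RIDGE = 1e-8


@dataclass(frozen=True)
class SwbdlParams:
    """swbDL tuning parameters."""

    lambda2: float = 8.0
    alpha: float = 1.0
    beta: float = 1.0  # ADMM tuning parameter
    iters: int = 15
    admm_iters: int = 30
    admm_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda2 < 0 or self.alpha < 0:
            raise ValueError("weights must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class AdmmState:
    """ADMM relaxation variable, multiplier and lagged dictionary."""

    U: np.ndarray
    W: np.ndarray
    D_0: np.ndarray
    residuals: list = field(default_factory=list)  # ||D_m - U||_F, last call


@dataclass
class SWModel:
    """Subject-wise representation model over multi-subject bases."""

    A: np.ndarray  # MP x K
    B: np.ndarray  # K x MP
    D_q: np.ndarray
    X_q: np.ndarray
    objective_trace: np.ndarray
    constraint_trace: list = field(default_factory=list)
    algorithm: str = "swbdl"

    @property
    def D(self) -> np.ndarray:
        """Subject dictionary D = D_q A."""
        return self.D_q @ self.A

    @property
    def X(self) -> np.ndarray:
        """Subject sparse code X = B X_q."""
        return self.B @ self.X_q

    @property
    def n_atoms(self) -> int:
        return self.A.shape[1]

    def summary(self) -> str:
        D = self.D
        lines = [
            f"{self.algorithm} subject-wise model",
            "-" * 40,
            f"atoms (K):              {self.n_atoms}",
            f"base size (MP):         {self.A.shape[0]}",
            f"iterations:             {len(self.objective_trace)}",
            f"final objective:        {self.objective_trace[-1]:.6g}",
            f"code sparsity:          {float(np.mean(self.X == 0)):.3f}",
            f"max |1 - ||D_q a_k||_2|: {float(np.max(np.abs(np.linalg.norm(D, axis=0) - 1))):.2e}",
        ]
        return "\n".join(lines)


def lag_dictionary(D: np.ndarray) -> np.ndarray:
    """Lag-1 delayed dictionary: shift columns down one sample.

    The first sample repeats the original first sample; columns are
    renormalised to unit norm.
    """
    if D.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    D0 = np.vstack([D[:1], D[:-1]])
    norms = np.linalg.norm(D0, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    return D0 / norms


def block_code_update(Y: np.ndarray, D_m: np.ndarray, lam2: float) -> np.ndarray:
    """Plain soft-threshold code: row k = S_{lam2/2}(d_k^T Y)."""
    return soft_threshold(D_m.T @ Y, 0.5 * lam2)


def fit_b(X_m: np.ndarray, X_q: np.ndarray, ridge: float = _RIDGE) -> np.ndarray:
    """Least-squares representation B = X_m X_q^T (X_q X_q^T + eps I)^-1."""
    if ridge is None:
        G = X_q @ X_q.T
        try:
            return np.linalg.solve(G, X_q @ X_m.T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "X_q X_q^T is singular and ridge is disabled"
            ) from exc
    return ridge_solve(X_q @ X_q.T, X_q @ X_m.T, ridge).T


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    return M / norms


def admm_dictionary(Y: np.ndarray, X_m: np.ndarray, D_0: np.ndarray,
                    params: SwbdlParams, state: AdmmState | None = None):
    """ADMM solve of the dictionary subproblem with autocorrelation penalty.

        D_m = (Y X_m^T + beta U - W)(X_m X_m^T + beta I)^-1
        U   = (alpha U U^T + beta I - alpha D_0 D_0^T)^-1 (beta D_m + W)
        W   = W + beta (D_m - U)

    The U-update linearises the self-referential optimality condition by
    using the previous U inside the inverse.  Columns of D_m and U are
    renormalised each iteration; stops after ``admm_iters`` or when both the
    primal residual ||D_m - U||_F and the dual residual beta ||U - U_prev||_F
    fall below admm_tol.  Returns (D_m, state) with the state suitable for
    warm-starting the next outer iteration.
    """
    N, K = Y.shape[0], X_m.shape[0]
    a, b = params.alpha, params.beta
    if state is None:
        state = AdmmState(U=np.zeros((N, K)), W=np.zeros((N, K)), D_0=D_0)
    else:
        state.D_0 = D_0
    U, W = state.U, state.W
    state.residuals = []
    Gx = X_m @ X_m.T + b * np.eye(K)
    YXt = Y @ X_m.T
    D_m = np.zeros((N, K))
    for _ in range(params.admm_iters):
        U_prev = U
        D_m = np.linalg.solve(Gx.T, (YXt + b * U - W).T).T
        D_m = _normalize_columns(D_m)
        M = a * (U @ U.T) + b * np.eye(N) - a * (D_0 @ D_0.T)
        try:
            U = np.linalg.solve(M, b * D_m + W)
        except np.linalg.LinAlgError:
            logger.warning("singular U-update system; adding ridge")
            U = ridge_solve(M, b * D_m + W, 1e-6)
        U = _normalize_columns(U)
        W = W + b * (D_m - U)
        resid = float(np.linalg.norm(D_m - U))
        dual = b * float(np.linalg.norm(U - U_prev))
        state.residuals.append(resid)
        if resid < params.admm_tol and dual < params.admm_tol:
            break
    state.U, state.W = U, W
    return D_m, state


def project_a(D_q: np.ndarray, D_m: np.ndarray, ridge: float = _RIDGE) -> np.ndarray:
    """Project the dictionary onto the base: A = (D_q^T D_q)^-1 D_q^T D_m.

    Each column is rescaled so that ||D_q a_k||_2 = 1; an exactly zero
    projection is rejected (the atom has no representation in the base).
    """
    A = ridge_solve(D_q.T @ D_q, D_q.T @ D_m, ridge)
    norms = np.linalg.norm(D_q @ A, axis=0)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"atom(s) {bad.tolist()} project to zero in the base")
    return A / norms


def init_representation(D_q: np.ndarray, D_init: np.ndarray) -> np.ndarray:
    """Project an initial dictionary onto the base, with indicator fallback.

    Columns of ``D_init`` that have (numerically) no representation in the
    base — e.g. a constant DCT atom against zero-mean base time courses —
    fall back to the indicator of the same-index base column.
    """
    A = ridge_solve(D_q.T @ D_q, D_q.T @ D_init, _RIDGE)
    norms = np.linalg.norm(D_q @ A, axis=0)
    MP = D_q.shape[1]
    for k in np.flatnonzero(norms < 1e-10):
        logger.info("init atom %d has no base representation; using base column", k)
        A[:, k] = 0.0
        A[k % MP, k] = 1.0
        norms[k] = np.linalg.norm(D_q[:, k % MP])
    return A / norms


def _objective(Y, D, X, D_0, lam2, alpha):
    rec = float(np.sum((Y - D @ X) ** 2))
    auto = float(np.sum((D @ D.T - D_0 @ D_0.T) ** 2))
    return rec + alpha * auto + lam2 * float(np.sum(np.abs(X)))


class SubjectwiseBlockDL:
    """swbDL model for one subject over multi-subject bases (D_q, X_q)."""

    def __init__(self, Y: SubjectMatrix | np.ndarray, D_q: np.ndarray,
                 X_q: np.ndarray, n_atoms: int = 9,
                 params: SwbdlParams | None = None,
                 D_init: np.ndarray | None = None, **kwargs):
        self.Y = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
        self.D_q = np.asarray(D_q, dtype=float)
        self.X_q = np.asarray(X_q, dtype=float)
        if self.D_q.shape[1] != self.X_q.shape[0]:
            raise ValueError("D_q columns must match X_q rows")
        if n_atoms > self.Y.shape[0]:
            raise ValueError("n_atoms must not exceed the number of scans")
        self.n_atoms = n_atoms
        self.params = params if params is not None else SwbdlParams(**kwargs)
        self.D_init = D_init

    def fit(self) -> SWModel:
        return run_swbdl(self.Y, self.D_q, self.X_q, self.params,
                         n_atoms=self.n_atoms, D_init=self.D_init)


def run_swbdl(Y, D_q, X_q, params: SwbdlParams,
              D_init: np.ndarray | None = None, n_atoms: int | None = None) -> SWModel:
    """Run swbDL outer iterations; returns an :class:`SWModel`.

    Per outer iteration: soft-threshold code -> least-squares B ->
    X_m = B X_q -> lag-1 D_0 from the current dictionary -> ADMM dictionary
    update (warm-started) -> projection to A -> D_m = D_q A.
    """
    from .ssbss import dct_basis

    A_data = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
    N = A_data.shape[0]
    if D_init is None:
        if n_atoms is None:
            raise ValueError("need n_atoms or D_init")
        D_m = dct_basis(N, n_atoms)
    else:
        D_m = _normalize_columns(np.array(D_init, dtype=float))
    K = D_m.shape[1]
    state = None
    trace = []
    cons = []
    A_rep = init_representation(D_q, D_m)
    B_rep = np.zeros((K, X_q.shape[0]))
    D_m = _normalize_columns(D_q @ A_rep)
    for _ in range(params.iters):
        X_thr = block_code_update(A_data, D_m, params.lambda2)
        B_rep = fit_b(X_thr, X_q)
        X_m = B_rep @ X_q
        D_0 = lag_dictionary(D_m)
        D_prev = D_m
        D_m, state = admm_dictionary(A_data, X_m, D_0, params, state)
        # dead-atom policy: a fully shrunk code row zeroes its column in the
        # ADMM solve; retain the previous atom instead
        dead = np.linalg.norm(D_m, axis=0) < 1e-10
        if dead.any():
            logger.debug("retaining %d dead atom(s)", int(dead.sum()))
            D_m[:, dead] = D_prev[:, dead]
            state.U[:, dead] = D_prev[:, dead]
            state.W[:, dead] = 0.0
        A_rep = project_a(D_q, D_m)
        D_m = D_q @ A_rep
        trace.append(_objective(A_data, D_m, X_m, D_0, params.lambda2, params.alpha))
        cons.append(
            {"unit_norm_dev": float(np.max(np.abs(np.linalg.norm(D_m, axis=0) - 1.0)))}
        )
    return SWModel(A=A_rep, B=B_rep, D_q=D_q, X_q=X_q,
                   objective_trace=np.asarray(trace), constraint_trace=cons,
                   algorithm="swbdl")
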