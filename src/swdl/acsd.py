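"""Adaptive consistent sequential dictionary learning (ACSD).

Solves, for one subject's data matrix Y (N x V),

    min_{D, X} ||Y - D X||_F^2 + sum_{k,j} lambda_j^k |x_j^k|
    s.t. ||d_k||_2 = 1

by sequential rank-1 pair updates: for each atom k the code row is an
adaptive soft threshold of d_k^T E_k (per-entry penalty
lambda_j^k = lambda / |d_k^T E_k|_j), and the atom is the normalised
projection of the error matrix onto the new code row.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from ._utils import TINY, adaptive_soft_threshold
from .preprocess import SubjectMatrix
from .ssbss import dct_basis

logger = logging.getLogger(__name__)

__all__ = ["DictModel", "AdaptiveConsistentDL", "adaptive_threshold_row",
           "acsd_update_pair", "run_acsd"]


def adaptive_threshold_row(z: np.ndarray, lam: float) -> np.ndarray:
    """Adaptive soft threshold sgn(z)*(|z| - (lam/2)/|z|)_+ (tiny |z| -> 0)."""
    return adaptive_soft_threshold(z, lam)


def acsd_update_pair(E_k: np.ndarray, d_k: np.ndarray, lam: float):
    """Joint rank-1 update of one atom / code-row pair.

    x^k = adaptive threshold of d_k^T E_k; d_k = E_k x^k^T normalised.
    A zero code row leaves the atom unchanged (dead-atom policy: retain).
    """
    x = adaptive_threshold_row(d_k @ E_k, lam)
    nx = np.linalg.norm(x)
    if nx == 0:
        logger.debug("zero code row; atom retained")
        return d_k, x
    d_new = E_k @ x
    nd = np.linalg.norm(d_new)
    if nd < TINY:
        return d_k, x
    return d_new / nd, x


@dataclass
class DictModel:
    """Learned dictionary (unit-norm atoms) and sparse code."""

    D: np.ndarray  # N x K
    X: np.ndarray  # K x V
    objective_trace: np.ndarray
    constraint_trace: list = field(default_factory=list)
    lam: float = 0.0

    @property
    def n_atoms(self) -> int:
        return self.D.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.D @ self.X

    def summary(self) -> str:
        lines = [
            "ACSD dictionary model",
            "-" * 40,
            f"atoms (K):            {self.n_atoms}",
            f"lambda:               {self.lam}",
            f"iterations:           {len(self.objective_trace)}",
            f"final objective:      {self.objective_trace[-1]:.6g}",
            f"code sparsity:        {float(np.mean(self.X == 0)):.3f}",
            f"max |1 - ||d_k||_2|:  {float(np.max(np.abs(np.linalg.norm(self.D, axis=0) - 1))):.2e}",
        ]
        return "\n".join(lines)


class AdaptiveConsistentDL:
    """ACSD model for one subject; ``fit`` returns a :class:`DictModel`.

    The dictionary is initialised with the first K DCT-II bases unless an
    explicit ``D_init`` is given.
    """

    def __init__(self, Y: SubjectMatrix | np.ndarray, n_atoms: int = 9,
                 lam: float = 12.0, iters: int = 15,
                 D_init: np.ndarray | None = None):
        self.Y = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
        if n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        self.n_atoms = n_atoms
        self.lam = lam
        self.iters = iters
        self.D_init = D_init

    def fit(self, rng: np.random.Generator | int | None = None) -> DictModel:
        return run_acsd(self.Y, self.n_atoms, self.lam, self.iters,
                        D_init=self.D_init, rng=rng)


def _objective(Y, D, X, lam, xi_abs):
    """Penalised objective with the adaptive weights frozen at update time."""
    pen = 0.0
    for k in range(D.shape[1]):
        w = np.where(xi_abs[k] < TINY, 0.0, lam / np.maximum(xi_abs[k], TINY))
        pen += float(np.sum(w * np.abs(X[k])))
    return float(np.sum((Y - D @ X) ** 2)) + pen


def run_acsd(Y, K: int, lam: float, iters: int,
             D_init: np.ndarray | None = None,
             rng: np.random.Generator | int | None = None) -> DictModel:
    """Run ACSD: ``iters`` sequential sweeps of K pair updates.

    The residual R = Y - D X is maintained incrementally; E_k = R + d_k x^k.
    The recorded objective uses the adaptive penalty weights frozen at
    their update-time values.
    """
    A = Y.data if isinstance(Y, SubjectMatrix) else np.asarray(Y, dtype=float)
    N, V = A.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if D_init is None:
        D = dct_basis(N, K)
    else:
        D = np.array(D_init, dtype=float)
        norms = np.linalg.norm(D, axis=0)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise ValueError("D_init columns must be unit-norm")
    X = np.zeros((K, V))
    R = A - D @ X
    trace = []
    cons = []
    xi_abs = np.zeros((K, V))
    for _ in range(iters):
        for k in range(K):
            E_k = R + np.outer(D[:, k], X[k])
            xi_abs[k] = np.abs(D[:, k] @ E_k)
            d_new, x_new = acsd_update_pair(E_k, D[:, k], lam)
            D[:, k] = d_new
            X[k] = x_new
            R = E_k - np.outer(d_new, x_new)
        trace.append(_objective(A, D, X, lam, xi_abs))
        cons.append(
            {"unit_norm_dev": float(np.max(np.abs(np.linalg.norm(D, axis=0) - 1.0)))}
        )
    return DictModel(D=D, X=X, objective_trace=np.asarray(trace),
                     constraint_trace=cons, lam=lam)
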