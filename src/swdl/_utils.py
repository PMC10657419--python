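"""Small shared numerics: thresholding operators, ridge solves, supports."""
from __future__ import annotations

import numpy as np

# guard for adaptive thresholds whose scale is 1/|z|
TINY = float(np.sqrt(np.finfo(float).eps))


def soft_threshold(z: np.ndarray, thresh: float) -> np.ndarray:
    """Plain soft threshold sgn(z) * (|z| - thresh)_+ ."""
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - thresh, 0.0)


def adaptive_soft_threshold(z: np.ndarray, lam: float) -> np.ndarray:
    """Adaptive threshold sgn(z) * (|z| - (lam/2)/|z|)_+ .

    The per-entry threshold (lam/2)/|z_j| shrinks large entries little and
    kills small ones; entries with |z_j| below the machine guard map to 0.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    z = np.asarray(z, dtype=float)
    az = np.abs(z)
    safe = np.where(az < TINY, 1.0, az)
    out = np.sign(z) * np.maximum(az - 0.5 * lam / safe, 0.0)
    out[az < TINY] = 0.0
    return out


def top_k_support(v: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest |v| entries; ties broken toward lower index."""
    v = np.asarray(v)
    if k >= v.size:
        return np.arange(v.size)
    order = np.argsort(-np.abs(v), kind="stable")
    return np.sort(order[:k])


def ridge_solve(G: np.ndarray, B: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Solve (G + eps*I) X = B for symmetric positive semidefinite G."""
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    try:
        return np.linalg.solve(G + eps * np.eye(n), B)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(G + eps * np.eye(n), B, rcond=None)[0]


def abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute Pearson correlation; 0 if either vector has zero variance."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(abs(a @ b) / (na * nb))


def abs_corr_matrix(cands: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """|Pearson| between every candidate row and reference row.

    Zero-variance vectors yield correlation 0 against everything.
    """
    C = np.asarray(cands, dtype=float)
    R = np.asarray(refs, dtype=float)
    C = C - C.mean(axis=1, keepdims=True)
    R = R - R.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(C, axis=1)
    rn = np.linalg.norm(R, axis=1)
    cn_safe = np.where(cn == 0, 1.0, cn)
    rn_safe = np.where(rn == 0, 1.0, rn)
    M = np.abs((C / cn_safe[:, None]) @ (R / rn_safe[:, None]).T)
    M[cn == 0, :] = 0.0
    M[:, rn == 0] = 0.0
    return M
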