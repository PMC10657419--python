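"""Loading, masking and temporal preprocessing of fMRI data matrices.

A subject's 4-D volume is reshaped to an N scans x V voxels matrix
(`SubjectMatrix`).  Temporal preprocessing follows the common fMRI recipe:
a DCT-based high-pass filter (regression projection onto low-frequency
DCT-II regressors, including the constant), a Gaussian low-pass filter
parameterised by its FWHM in seconds, and per-voxel standardisation to
zero mean / unit variance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class SubjectMatrix:
    """One subject's scans x voxels data matrix with acquisition metadata."""

    data: np.ndarray
    tr: float
    subject_id: str = ""
    voxel_index: np.ndarray | None = None  # columns -> flat mask voxel indices
    mask_shape: tuple | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (scans x voxels)")
        if self.data.shape[0] < 2 or self.data.shape[1] < 1:
            raise ValueError("need at least 2 scans and 1 voxel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def load_mask_reshape(volume_path, mask_path, tr: float | None = None,
                      subject_id: str = "") -> SubjectMatrix:
    """Load a 4-D NIfTI volume, apply a 3-D binary mask, reshape to N x V.

    Columns follow grid-major order of the mask's true voxels (first grid
    axis fastest), which is stable and invertible via ``voxel_index``.
    """
    import nibabel as nib

    img = nib.load(str(volume_path))
    msk = nib.load(str(mask_path))
    vol = np.asanyarray(img.dataobj)
    mask = np.asanyarray(msk.dataobj)
    if vol.ndim != 4:
        raise ValueError("volume must be 4-D")
    if mask.shape != vol.shape[:3]:
        raise ValueError("mask grid does not match the volume grid")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("mask must be binary (0/1)")
    mask = mask.astype(bool)
    flat_mask = mask.reshape(-1, order="F")  # x fastest
    vox_idx = np.flatnonzero(flat_mask)
    n_scans = vol.shape[3]
    flat = vol.reshape(-1, n_scans, order="F")  # (voxels, scans)
    data = flat[vox_idx, :].T.astype(float)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return SubjectMatrix(
        data=data,
        tr=tr,
        subject_id=subject_id,
        voxel_index=vox_idx,
        mask_shape=tuple(mask.shape),
    )


def matrix_to_volume(sm: SubjectMatrix) -> np.ndarray:
    """Write the matrix back through its mask to a 4-D array (inverse of load)."""
    if sm.voxel_index is None or sm.mask_shape is None:
        raise ValueError("SubjectMatrix lacks mask provenance")
    n_vox_total = int(np.prod(sm.mask_shape))
    flat = np.zeros((n_vox_total, sm.n_scans))
    flat[sm.voxel_index, :] = sm.data.T
    return flat.reshape(sm.mask_shape + (sm.n_scans,), order="F")


def dct_regressors(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal DCT-II regressors with frequency below ``cutoff_hz``.

    Basis vector j (j = 0 constant) has frequency j / (2 N TR); the
    number of regressors returned is floor(2 N TR cutoff) + 1.
    """
    n_reg = int(np.floor(2.0 * n * tr * cutoff_hz)) + 1
    from .ssbss import dct_basis

    return dct_basis(n, n_reg)


def dct_highpass(Y: SubjectMatrix, cutoff_hz: float) -> SubjectMatrix:
    """Project out low-frequency DCT trends (including the constant).

    Implemented as regression residualisation against the DCT-II
    regressors below the cutoff, which makes the filter an idempotent
    linear projector.
    """
    nyquist = 1.0 / (2.0 * Y.tr)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    R = dct_regressors(Y.n_scans, Y.tr, cutoff_hz)
    resid = Y.data - R @ (R.T @ Y.data)
    return replace(Y, data=resid)


def gaussian_lowpass(Y: SubjectMatrix, fwhm_sec: float) -> SubjectMatrix:
    """Temporal Gaussian smoothing with the given FWHM (seconds).

    Unit-sum kernel, sigma = FWHM / 2.3548 converted to samples via the TR,
    reflective boundary handling.
    """
    if fwhm_sec <= 0:
        raise ValueError("fwhm_sec must be positive")
    sigma_samples = fwhm_sec / FWHM_TO_SIGMA / Y.tr
    sm = gaussian_filter1d(Y.data, sigma=sigma_samples, axis=0, mode="reflect")
    return replace(Y, data=sm)


def normalize_columns(Y: SubjectMatrix) -> SubjectMatrix:
    """Standardise every voxel time series to zero mean, unit (n-1) variance.

    Constant columns are mapped to zero with a logged warning.
    """
    X = Y.data - Y.data.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    const = sd[0] == 0
    if const.any():
        logger.warning("%d constant column(s) mapped to zero", int(const.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    X = X / sd
    X[:, const] = 0.0
    return replace(Y, data=X)
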