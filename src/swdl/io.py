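"""HDF5 matrix-container and NIfTI export helpers."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import SubjectMatrix
from .synthgen import GroundTruth, SyntheticDataset

__all__ = [
    "save_subject",
    "load_subject",
    "save_dataset",
    "save_bases",
    "load_bases",
    "export_maps_nifti",
]


def save_subject(path, subject: SubjectMatrix, truth: GroundTruth | None = None,
                 metadata: dict | None = None) -> None:
    """Write one subject (Y, optional ground truth, metadata) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=subject.data)
        f.attrs["tr"] = subject.tr
        f.attrs["subject_id"] = subject.subject_id
        if truth is not None:
            f.create_dataset("tcs", data=truth.tcs)
            f.create_dataset("sms", data=truth.sms)
            f.attrs["sharing_labels"] = json.dumps(truth.sharing_labels)
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata)


def load_subject(path):
    """Read a subject container; returns (SubjectMatrix, GroundTruth|None, meta)."""
    with h5py.File(path, "r") as f:
        sub = SubjectMatrix(
            data=f["Y"][()],
            tr=float(f.attrs["tr"]),
            subject_id=str(f.attrs.get("subject_id", "")),
        )
        truth = None
        if "tcs" in f:
            truth = GroundTruth(
                tcs=f["tcs"][()],
                sms=f["sms"][()],
                sharing_labels=json.loads(f.attrs["sharing_labels"]),
            )
        meta = json.loads(f.attrs["metadata"]) if "metadata" in f.attrs else {}
    return sub, truth, meta


def save_dataset(outdir, ds: SyntheticDataset) -> list[Path]:
    """Write one container per subject plus the group truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sub, truth in zip(ds.subjects, ds.truths):
        p = outdir / f"{sub.subject_id}.h5"
        save_subject(p, sub, truth, ds.metadata)
        paths.append(p)
    gpath = outdir / "group_truth.h5"
    with h5py.File(gpath, "w") as f:
        f.create_dataset("tcs", data=ds.group_truth.tcs)
        f.create_dataset("sms", data=ds.group_truth.sms)
        f.attrs["sharing_labels"] = json.dumps(ds.group_truth.sharing_labels)
        f.attrs["metadata"] = json.dumps(ds.metadata)
    paths.append(gpath)
    return paths


def save_bases(path, D_q: np.ndarray, X_q: np.ndarray, provenance=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("D_q", data=D_q)
        f.create_dataset("X_q", data=X_q)
        if provenance is not None:
            f.create_dataset("provenance", data=np.asarray(provenance))


def load_bases(path):
    from .framework import BaseMatrices

    with h5py.File(path, "r") as f:
        prov = f["provenance"][()].tolist() if "provenance" in f else []
        return BaseMatrices(D_q=f["D_q"][()], X_q=f["X_q"][()], provenance=prov)


def export_maps_nifti(path, sms: np.ndarray, grid: tuple[int, int]) -> None:
    """Export P x V spatial maps as a (gx, gy, 1, P) NIfTI with identity affine."""
    import nibabel as nib

    gx, gy = grid
    vol = sms.T.reshape(gx, gy, 1, sms.shape[0], order="C")
    nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), str(path))
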