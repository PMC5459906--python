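"""Standard-format I/O: NIfTI-1 volumes, SPM motion files, participants tables."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldSeries, MetricMap

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_motion_params",
    "write_motion_params",
    "read_participants",
    "write_cohort",
]

VALID_GROUPS = {"ADHD", "TDC"}


def write_nifti(obj, path: str) -> str:
    """Write a BoldSeries, MetricMap, mask or raw array as NIfTI-1.

    BOLD data is stored float32 with TR in pixdim[4]; the affine is kept
    exactly.
    """
    if isinstance(obj, BoldSeries):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
        zooms = img.header.get_zooms()
        img.header.set_zooms((*zooms[:3], float(obj.tr_seconds)))
        img.header.set_xyzt_units("mm", "sec")
    elif isinstance(obj, MetricMap):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
    else:
        arr = np.asarray(obj)
        dtype = np.uint8 if arr.dtype == bool else np.float32
        img = nib.Nifti1Image(arr.astype(dtype), np.eye(4))
    nib.save(img, path)
    return path


def read_nifti(path: str, tr_seconds: float | None = None):
    """Read NIfTI-1 (.nii or .nii.gz): 4D -> BoldSeries, 3D -> (data, affine).

    The TR comes from pixdim[4] unless overridden; a missing/zero header TR
    without an override is rejected with header diagnostics.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=float)
        affine = img.affine
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"cannot read NIfTI {path!r}: {exc}") from exc
    if data.ndim == 4:
        if tr_seconds is None:
            zooms = img.header.get_zooms()
            tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
            if tr_seconds <= 0:
                raise ValueError(
                    f"{path}: no usable TR in pixdim[4] (zooms={zooms}); "
                    "pass tr_seconds explicitly"
                )
        return BoldSeries(data, affine, tr_seconds)
    return data, affine


def write_motion_params(motion6: np.ndarray, path: str) -> str:
    """Write an SPM-style rp_*.txt: 6 whitespace-delimited columns."""
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError("motion table must be (T, 6)")
    np.savetxt(path, motion6, fmt="%.10e")
    return path


def read_motion_params(path: str) -> np.ndarray:
    """Read an SPM rp_*.txt motion file (translations mm, rotations rad)."""
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got shape {motion.shape}")
    return motion


def read_participants(path: str) -> pd.DataFrame:
    """Read and validate a BIDS-like participants.tsv.

    Requires columns participant_id, group, cohort, iq; group labels must be
    ADHD/TDC; duplicate participant_id is rejected; extra columns pass
    through untouched.
    """
    table = pd.read_csv(path, sep="\t")
    for col in ("participant_id", "group", "cohort", "iq"):
        if col not in table.columns:
            raise ValueError(f"participants table missing required column {col!r}")
    bad = set(table["group"].astype(str)) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {sorted(VALID_GROUPS)}")
    if table["participant_id"].duplicated().any():
        dups = table.loc[table["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"duplicate participant_id: {dups}")
    return table


def write_cohort(dataset, out_dir: str) -> dict:
    """Write one simulated cohort as NIfTI + rp_*.txt + participants.tsv."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {"subjects": {}}
    for sub in dataset.subjects:
        bold_path = os.path.join(out_dir, f"{sub.subject_id}_bold.nii.gz")
        rp_path = os.path.join(out_dir, f"rp_{sub.subject_id}.txt")
        write_nifti(sub.bold, bold_path)
        write_motion_params(sub.motion, rp_path)
        paths["subjects"][sub.subject_id] = {"bold": bold_path, "motion": rp_path}
    for name in ("brain_mask", "gm_mask", "wm_mask", "csf_mask"):
        p = os.path.join(out_dir, f"{name}.nii.gz")
        write_nifti(getattr(dataset, name), p)
        paths[name] = p
    tsv = os.path.join(out_dir, "participants.tsv")
    dataset.participants.to_csv(tsv, sep="\t", index=False)
    paths["participants"] = tsv
    return paths
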