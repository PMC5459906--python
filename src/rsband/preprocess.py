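"""Post-normalization preprocessing: truncation, nuisance regression, motion.

Covers the steps applied to an already spatially-normalized series: dropping
the initial volumes, expanding the six rigid-body motion parameters to the
Friston-24 set, summarizing motion as Jenkinson's mean framewise displacement
(FD), extracting mean white-matter/CSF signals, and voxel-wise ordinary
least-squares removal of nuisance regressors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BoldSeries

__all__ = [
    "truncate_volumes",
    "friston24_expand",
    "rigid_transform",
    "mean_fd_jenkinson",
    "extract_tissue_signal",
    "build_confounds",
    "regress_nuisance",
]


def truncate_volumes(bold: BoldSeries, drop_first: int = 10, keep: int = 170) -> BoldSeries:
    """Drop the first ``drop_first`` volumes and keep the next ``keep``.

    The defaults discard 10 volumes for scanner equilibration and retain 170
    so cohorts with different run lengths stay comparable. Motion tables must
    be truncated identically by the caller.
    """
    have = bold.n_volumes
    if drop_first < 0 or keep < 1:
        raise ValueError("drop_first must be >= 0 and keep >= 1")
    if have < drop_first + keep:
        raise ValueError(
            f"cannot keep volumes [{drop_first}, {drop_first + keep}): "
            f"series has only {have} volumes"
        )
    return bold.with_data(
        bold.data[..., drop_first : drop_first + keep],
        step=f"truncate[{drop_first}:{drop_first + keep}]",
    )


def friston24_expand(motion6: np.ndarray) -> np.ndarray:
    """Friston-24 motion expansion: [p(t), p(t-1), p(t)^2, p(t-1)^2] x 6.

    Row 0 of each lagged block is defined as 0. Column layout is the four
    6-column blocks in the order above (24 columns total).
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"expected a (T, 6) motion table, got shape {motion6.shape}")
    lag = np.zeros_like(motion6)
    lag[1:] = motion6[:-1]
    return np.hstack([motion6, lag, motion6**2, lag**2])


def rigid_transform(params6: np.ndarray) -> np.ndarray:
    """4x4 rigid-body transform from 6 parameters (tx,ty,tz mm; rx,ry,rz rad).

    SPM convention: rotations about x, then y, then z (R = Rz @ Ry @ Rx),
    translations applied after rotation.
    """
    tx, ty, tz, rx, ry, rz = np.asarray(params6, dtype=float)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = (tx, ty, tz)
    return T


def fd_jenkinson(motion6: np.ndarray, sphere_radius_mm: float = 80.0) -> np.ndarray:
    """Per-frame framewise displacement, Jenkinson's RMS formulation.

    For consecutive frames with rigid transforms T_{i-1}, T_i the differential
    transform M = T_i T_{i-1}^{-1} - I has rotation part A and translation b;
    FD_i = sqrt(r^2/5 * trace(A^T A) + b^T b), the RMS displacement of points
    in a solid sphere of radius r centred at the origin. Frame 0 has FD 0.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"expected a (T, 6) motion table, got shape {motion6.shape}")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 time points for FD")
    if not np.isfinite(motion6).all():
        raise ValueError("motion parameters contain non-finite values")
    r2 = sphere_radius_mm**2
    fd = np.zeros(motion6.shape[0])
    T_prev = rigid_transform(motion6[0])
    for i in range(1, motion6.shape[0]):
        T_cur = rigid_transform(motion6[i])
        M = T_cur @ np.linalg.inv(T_prev) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[i] = np.sqrt(r2 / 5.0 * np.trace(A.T @ A) + b @ b)
        T_prev = T_cur
    return fd


def mean_fd_jenkinson(motion6: np.ndarray, sphere_radius_mm: float = 80.0) -> float:
    """Mean framewise displacement over frames 2..T (mm)."""
    return float(fd_jenkinson(motion6, sphere_radius_mm)[1:].mean())


def extract_tissue_signal(bold: BoldSeries, tissue_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean time course over the voxels of a tissue mask."""
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != bold.grid_shape:
        raise ValueError(
            f"tissue mask shape {tissue_mask.shape} does not match grid {bold.grid_shape}"
        )
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    return bold.data[tissue_mask].mean(axis=0)


def build_confounds(
    n_timepoints: int,
    motion6: np.ndarray | None = None,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the nuisance design: linear trend, Friston-24, WM, CSF.

    Any absent component is simply omitted; the linear trend is always
    present. Returns a (T, k) DataFrame with named columns.
    """
    cols: dict[str, np.ndarray] = {"trend": np.linspace(-0.5, 0.5, n_timepoints)}
    if motion6 is not None:
        motion6 = np.asarray(motion6, dtype=float)
        if motion6.shape[0] != n_timepoints:
            raise ValueError("motion table row count does not match time points")
        f24 = friston24_expand(motion6)
        blocks = ["mot", "mot_lag", "mot_sq", "mot_lag_sq"]
        for j in range(24):
            cols[f"{blocks[j // 6]}{j % 6 + 1}"] = f24[:, j]
    for name, sig in (("wm", wm_signal), ("csf", csf_signal)):
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (n_timepoints,):
                raise ValueError(f"{name} signal length does not match time points")
            cols[name] = sig
    return pd.DataFrame(cols)


def regress_nuisance(bold: BoldSeries, confounds: "pd.DataFrame | np.ndarray") -> BoldSeries:
    """Voxel-wise OLS removal of nuisance regressors, voxel means restored.

    Each voxel's time course is regressed on [intercept, confounds]; the
    residuals plus the voxel's temporal mean are returned, so downstream
    amplitude measures still see a physical baseline. Rank-deficient designs
    are handled by the pseudo-inverse.
    """
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    T = bold.n_volumes
    if C.shape[0] != T:
        raise ValueError(f"confounds have {C.shape[0]} rows but series has {T} volumes")
    X = np.column_stack([np.ones(T), C])
    Y = bold.data.reshape(-1, T).T  # (T, V)
    beta = np.linalg.pinv(X) @ Y  # rank-deficiency handled by the pseudo-inverse
    resid = Y - X @ beta
    out = (resid + Y.mean(axis=0)).T.reshape(bold.data.shape)
    return bold.with_data(out.astype(bold.data.dtype, copy=False), step="regress_nuisance")
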