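"""Core in-memory containers shared by every stage of the pipeline.

A :class:`BoldSeries` is one subject's 4D resting-state volume together with
its voxel-to-world affine, repetition time, and an append-only processing
history used to enforce ordering conventions (e.g. spatial smoothing before
ALFF but after ReHo/DC). A :class:`MetricMap` is the 3D voxel-wise result of
one metric in one frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BoldSeries", "MetricMap", "MISSING"]

#: designated missing value for out-of-mask voxels in metric maps
MISSING = np.nan


@dataclass
class BoldSeries:
    """One subject's 4D BOLD series (x, y, z, t) in a fixed voxel grid.

    Parameters
    ----------
    data
        4D float array, time last.
    affine
        4x4 voxel-to-world transform in mm.
    tr_seconds
        Repetition time (volume-to-volume sampling interval), seconds.
    meta
        Provenance tags. ``meta["history"]`` is the append-only list of
        processing-step names applied so far.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        self.meta.setdefault("history", [])

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def history(self) -> list[str]:
        return self.meta["history"]

    def with_data(self, data: np.ndarray, step: str | None = None) -> "BoldSeries":
        """Copy carrying new data; append ``step`` to the processing history."""
        meta = {**self.meta, "history": list(self.meta["history"])}
        if step is not None:
            meta["history"].append(step)
        return replace(self, data=np.asarray(data), meta=meta)

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


@dataclass
class MetricMap:
    """A voxel-wise 3D metric map (ALFF, ReHo or DC) on a brain mask.

    Out-of-mask voxels hold :data:`MISSING` (NaN).
    """

    data: np.ndarray
    metric: str
    band: str
    mask: np.ndarray
    affine: np.ndarray
    smoothed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("metric map must be 3D")
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")
        if self.metric not in ("ALFF", "ReHo", "DC"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def in_mask(self) -> np.ndarray:
        """1D array of metric values at in-mask voxels."""
        return self.data[self.mask]
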