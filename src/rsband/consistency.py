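"""Cross-cohort consistency: overlap counts, Dice, pooled-vs-cohort categories.

The Dice coefficient here is the *study's* variant: the number of voxels in
the intersection of all N cohort maps divided by the SUM of the voxel counts
of every cohort map. This is not the classical 2|A∩B|/(|A|+|B|): for two
maps it equals classical Dice / 2, and for N identical maps its maximum is
1/N. It is deliberately implemented as stated, and flagged as non-classical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .groupstats import connectivity_structure

__all__ = [
    "overlap_count",
    "dice_overlap",
    "classical_dice",
    "categorize_vs_pooled",
    "overlap_cluster_table",
    "OverlapReport",
    "CATEGORY_CODES",
]


def _check_common_grid(maps) -> list[np.ndarray]:
    maps = [np.asarray(m, dtype=bool) for m in maps]
    if not maps:
        raise ValueError("no maps given")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("maps are not on a common grid")
    return maps


def overlap_count(binmaps) -> np.ndarray:
    """Voxel-wise count of cohorts flagging each voxel."""
    maps = _check_common_grid(binmaps)
    return np.sum(maps, axis=0).astype(int)


def dice_overlap(binmaps) -> float:
    """|intersection of all maps| / sum over cohorts of |map| (study variant).

    Maximum 1/N for N maps; 0 for disjoint maps; all-empty input returns 0.
    """
    maps = _check_common_grid(binmaps)
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    total = sum(int(m.sum()) for m in maps)
    if total == 0:
        return 0.0
    inter = maps[0].copy()
    for m in maps[1:]:
        inter &= m
    return float(inter.sum() / total)


def classical_dice(a, b) -> float:
    """Classical two-set Dice 2|A∩B| / (|A|+|B|), for cross-checking."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps are not on a common grid")
    denom = int(a.sum()) + int(b.sum())
    return 0.0 if denom == 0 else float(2 * (a & b).sum() / denom)


#: Category codes for the pooled-vs-cohorts comparison of flagged voxels.
#: (cohort count, flagged in pooled?) -> code
CATEGORY_CODES = {
    "pooled_only": 1,
    "cohort1_only": 2,
    "cohorts2_only": 3,
    "pooled_and_1": 4,
    "pooled_and_2": 5,
    "pooled_and_3plus": 6,
    "cohorts3plus_only": 7,
}


def categorize_vs_pooled(cohort_binmaps, pooled_binmap):
    """Classify every flagged voxel by (number of cohorts, pooled membership).

    Returns ``(category_map, counts)`` where ``category_map`` holds the codes
    of :data:`CATEGORY_CODES` (0 = unflagged) and ``counts`` is a per-category
    voxel-count Series. The categories are mutually exclusive and together
    cover exactly the union of all maps.
    """
    maps = _check_common_grid(cohort_binmaps)
    pooled = np.asarray(pooled_binmap, dtype=bool)
    if pooled.shape != maps[0].shape:
        raise ValueError("pooled map grid mismatch")
    count = overlap_count(maps)
    cat = np.zeros(pooled.shape, dtype=int)
    cat[pooled & (count == 0)] = CATEGORY_CODES["pooled_only"]
    cat[~pooled & (count == 1)] = CATEGORY_CODES["cohort1_only"]
    cat[~pooled & (count == 2)] = CATEGORY_CODES["cohorts2_only"]
    cat[pooled & (count == 1)] = CATEGORY_CODES["pooled_and_1"]
    cat[pooled & (count == 2)] = CATEGORY_CODES["pooled_and_2"]
    cat[pooled & (count >= 3)] = CATEGORY_CODES["pooled_and_3plus"]
    cat[~pooled & (count >= 3)] = CATEGORY_CODES["cohorts3plus_only"]
    counts = pd.Series(
        {name: int((cat == code).sum()) for name, code in CATEGORY_CODES.items()},
        name="n_voxels",
    )
    return cat, counts


def overlap_cluster_table(
    count_map: np.ndarray,
    min_level: int,
    connectivity: int = 26,
    binmaps=None,
    affine: np.ndarray | None = None,
) -> pd.DataFrame:
    """Clusters of voxels flagged by at least ``min_level`` cohorts.

    One row per cluster, sorted by size descending, with peak world
    coordinates (the peak is the in-cluster voxel of maximal overlap count).
    If ``binmaps`` is given, each row also carries the study Dice restricted
    to the cluster's voxels (intersection counted within the cluster, the
    denominator remaining the whole-map cohort totals). When no cluster
    reaches ``min_level`` a single 'None' row is emitted.
    """
    count_map = np.asarray(count_map)
    n_cohorts = int(count_map.max(initial=0))
    if binmaps is not None:
        maps = _check_common_grid(binmaps)
        n_cohorts = len(maps)
    if not (2 <= min_level <= max(n_cohorts, 2)):
        raise ValueError(f"min_level must be in [2, {n_cohorts}]")
    if affine is None:
        affine = np.eye(4)
    structure = connectivity_structure(connectivity)
    supra = count_map >= min_level
    labels, n = ndimage.label(supra, structure=structure)
    rows = []
    for lab in range(1, n + 1):
        sel = labels == lab
        size = int(sel.sum())
        vals = np.where(sel, count_map, -1)
        peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
        peak_mm = affine @ np.array([*peak, 1.0])
        row = {
            "min_level": min_level,
            "n_voxels": size,
            "peak_x_mm": peak_mm[0],
            "peak_y_mm": peak_mm[1],
            "peak_z_mm": peak_mm[2],
            "max_count": int(count_map[peak]),
        }
        if binmaps is not None:
            # per-cluster Dice: the cluster's voxels (each overlapped by at
            # least min_level cohorts) over the whole-map cohort totals
            total = sum(int(m.sum()) for m in maps)
            row["dice"] = 0.0 if total == 0 else float(size / total)
        rows.append(row)
    cols = ["min_level", "n_voxels", "peak_x_mm", "peak_y_mm", "peak_z_mm", "max_count"]
    if binmaps is not None:
        cols.append("dice")
    if not rows:
        none_row = {c: np.nan for c in cols}
        none_row["min_level"] = min_level
        none_row["n_voxels"] = 0
        return pd.DataFrame([none_row], columns=cols)
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values("n_voxels", ascending=False)
        .reset_index(drop=True)
    )


@dataclass
class OverlapReport:
    """Per metric x band consistency summary across cohorts."""

    metric: str
    band: str
    cohort_binmaps: dict
    overlap_count_map: np.ndarray = None
    pooled_binmap: np.ndarray | None = None
    dice_all: float = np.nan
    category_map: np.ndarray | None = None
    category_counts: pd.Series | None = None
    cluster_tables: dict = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        metric: str,
        band: str,
        cohort_binmaps: dict,
        pooled_binmap: np.ndarray | None = None,
        connectivity: int = 26,
        affine: np.ndarray | None = None,
    ) -> "OverlapReport":
        maps = list(cohort_binmaps.values())
        count = overlap_count(maps)
        dice = dice_overlap(maps) if len(maps) >= 2 else np.nan
        cat_map = cat_counts = None
        if pooled_binmap is not None:
            cat_map, cat_counts = categorize_vs_pooled(maps, pooled_binmap)
        tables = {}
        n = len(maps)
        for level in range(max(2, n - 1), n + 1):
            tables[level] = overlap_cluster_table(
                count, level, connectivity=connectivity, binmaps=maps, affine=affine
            )
        return cls(
            metric=metric,
            band=band,
            cohort_binmaps=cohort_binmaps,
            overlap_count_map=count,
            pooled_binmap=pooled_binmap,
            dice_all=dice,
            category_map=cat_map,
            category_counts=cat_counts,
            cluster_tables=tables,
        )
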