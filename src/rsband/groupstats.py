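"""Group-level statistics: masks, voxel-wise GLM, effect sizes, cluster correction.

The group comparison is a per-voxel ordinary-least-squares model
[intercept, group, covariates] whose group-coefficient t statistic is
converted to a standardized effect size (Cohen's d) through

    d = t * sqrt((n1 + n2) / (n1 * n2))

Multiple comparisons are handled by cluster-extent correction: the minimum
cluster size k at corrected p is calibrated by Monte-Carlo simulation of
smooth Gaussian noise on the analysis mask (AlphaSim approach), with the
noise smoothness estimated from the GLM residual maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .metrics import smooth_gaussian

__all__ = [
    "GroupSample",
    "StatResult",
    "ClusterDecision",
    "build_group_mask",
    "pooled_mask",
    "glm_group_ttest",
    "t_to_d",
    "d_to_t",
    "two_sample_t",
    "estimate_smoothness",
    "monte_carlo_cluster_threshold",
    "threshold_statmap",
    "connectivity_structure",
]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structuring element for 6/18/26-connected clustering."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


# ---------------------------------------------------------------------------
# masks

def build_group_mask(subject_masks, coverage: float = 0.8, gm_mask=None) -> np.ndarray:
    """Voxels present in >= ``coverage`` of subjects, intersected with gray matter.

    The boundary is inclusive: with 5 subjects and coverage 0.8, presence in
    exactly 4 keeps the voxel.
    """
    masks = [np.asarray(m, dtype=bool) for m in subject_masks]
    if not masks:
        raise ValueError("need at least one subject mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("subject masks are not on a common grid")
    frac = np.mean(masks, axis=0)
    out = frac >= coverage - 1e-12
    if gm_mask is not None:
        gm_mask = np.asarray(gm_mask, dtype=bool)
        if gm_mask.shape != shape:
            raise ValueError("gray-matter mask grid mismatch")
        out &= gm_mask
    return out


def pooled_mask(cohort_masks) -> np.ndarray:
    """Intersection of the cohort analysis masks."""
    masks = [np.asarray(m, dtype=bool) for m in cohort_masks]
    if len(masks) < 2:
        raise ValueError("need at least two cohort masks to pool")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("cohort masks are not on a common grid")
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out


# ---------------------------------------------------------------------------
# effect sizes

def d_to_t(d: float, n_adhd: int, n_tdc: int) -> float:
    """Cohen's d to the equivalent two-sample t: t = d / sqrt((n1+n2)/(n1 n2))."""
    if n_adhd < 2 or n_tdc < 2:
        raise ValueError("both group sizes must be >= 2")
    return float(d / np.sqrt((n_adhd + n_tdc) / (n_adhd * n_tdc)))


def t_to_d(t, n_adhd: int, n_tdc: int):
    """Two-sample t to Cohen's d: d = t * sqrt((n1+n2)/(n1 n2)). Array-safe."""
    if n_adhd < 2 or n_tdc < 2:
        raise ValueError("both group sizes must be >= 2")
    factor = np.sqrt((n_adhd + n_tdc) / (n_adhd * n_tdc))
    out = np.asarray(t, dtype=float) * factor
    return float(out) if np.isscalar(t) else out


@dataclass
class GroupSample:
    """Per-voxel group summary with the pooled SD for Cohen's d."""

    mean_adhd: np.ndarray
    mean_tdc: np.ndarray
    sd_adhd: np.ndarray
    sd_tdc: np.ndarray
    n_adhd: int
    n_tdc: int

    @property
    def pooled_sd(self) -> np.ndarray:
        n1, n2 = self.n_adhd, self.n_tdc
        return np.sqrt(
            ((n1 - 1) * self.sd_adhd**2 + (n2 - 1) * self.sd_tdc**2) / (n1 + n2 - 2)
        )

    def cohens_d(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.mean_adhd - self.mean_tdc) / self.pooled_sd


def two_sample_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Closed-form pooled-variance two-sample t (x1 minus x2), vectorized.

    Kept as the no-covariate reference formula the GLM must agree with.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    n1, n2 = x1.shape[0], x2.shape[0]
    s1 = x1.std(axis=0, ddof=1)
    s2 = x2.std(axis=0, ddof=1)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x1.mean(axis=0) - x2.mean(axis=0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


@dataclass
class StatResult:
    """Voxel-wise group contrast: t map, residual df, Cohen's d (SES) map."""

    t_map: np.ndarray
    df: int
    ses_map: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    n_adhd: int
    n_tdc: int
    residuals: np.ndarray | None = None  # (subjects, voxels) in-mask residuals
    design_columns: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def glm_group_ttest(
    metric_maps,
    groups,
    covariates: "pd.DataFrame | None" = None,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    keep_residuals: bool = True,
) -> StatResult:
    """Voxel-wise two-sample comparison as an OLS GLM with covariates.

    Design: [intercept, group indicator (ADHD=1, TDC=0), mean-centered
    covariates]. t is the group coefficient over its standard error with
    df = n - p; positive t means ADHD > TDC. The SES map is the t map scaled
    per ``t_to_d``.

    ``metric_maps`` may be a list of MetricMap (a common ``mask`` is then
    required or taken from the first map) or an (n_subjects, n_voxels) array
    of in-mask values.
    """
    groups = np.asarray(
        [1 if str(g).upper() in ("1", "ADHD") else 0 for g in groups], dtype=float
    )
    n = groups.size
    n_adhd = int(groups.sum())
    n_tdc = n - n_adhd
    if n_adhd < 2 or n_tdc < 2:
        raise ValueError(f"need >= 2 subjects per group, got {n_adhd}/{n_tdc}")

    if isinstance(metric_maps, np.ndarray) and metric_maps.ndim == 2:
        Y = np.asarray(metric_maps, dtype=float)
        if mask is None:
            mask = np.ones(Y.shape[1], dtype=bool)
    else:
        maps = list(metric_maps)
        if mask is None:
            mask = maps[0].mask
        if affine is None:
            affine = maps[0].affine
        Y = np.stack([m.data[mask] for m in maps])
    if Y.shape[0] != n:
        raise ValueError("one metric map per subject required")
    if affine is None:
        affine = np.eye(4)

    cols = ["intercept", "group"]
    X = [np.ones(n), groups]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        if len(cov) != n:
            raise ValueError("covariate rows must match subjects")
        for name in cov.columns:
            c = cov[name].to_numpy(dtype=float)
            X.append(c - c.mean())
            cols.append(str(name))
    X = np.column_stack(X)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns for the error message
        bad = [
            cols[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"collinear design; redundant columns: {bad}")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    # voxels with numerically-zero residual variance (e.g. identical data in
    # both groups): t is 0/0 noise, defined as 0
    degenerate = sigma2 <= 1e-24 * ((Y**2).mean(axis=0) + np.finfo(float).tiny)
    t[degenerate] = 0.0

    if np.asarray(mask).ndim == 3:
        t_map = np.full(mask.shape, np.nan)
        t_map[mask] = t
    else:
        t_map = t
    ses = t_to_d(t_map, n_adhd, n_tdc)
    return StatResult(
        t_map=t_map,
        df=df,
        ses_map=ses,
        mask=np.asarray(mask),
        affine=affine,
        n_adhd=n_adhd,
        n_tdc=n_tdc,
        residuals=resid if keep_residuals else None,
        design_columns=cols,
    )


# ---------------------------------------------------------------------------
# smoothness + Monte-Carlo cluster-extent correction

def estimate_smoothness(residual_maps, mask, voxel_mm) -> np.ndarray:
    """Per-axis smoothness (FWHM, mm) of residual maps on a mask.

    Classical spatial-differencing estimator: with standardized residuals of
    variance v and neighbour-difference variance dv along an axis,
    FWHM = voxel * sqrt(-2 ln 2 / ln(1 - dv / (2 v))), averaged over maps.
    An axis with fewer than 2 in-mask neighbour pairs is reported as NaN;
    effectively unsmoothed data (dv >= 2v) estimates as 0.
    """
    mask = np.asarray(mask, dtype=bool)
    vox = np.broadcast_to(np.atleast_1d(np.asarray(voxel_mm, dtype=float)), (3,))
    maps = [np.asarray(m, dtype=float) for m in residual_maps]
    if len(maps) < 2:
        raise ValueError("need at least 2 residual maps")
    fwhm = np.full((len(maps), 3), np.nan)
    for i, m in enumerate(maps):
        vals = m[mask]
        sd = vals.std()
        if sd == 0:
            continue
        z = np.where(mask, (m - vals.mean()) / sd, np.nan)
        for ax in range(3):
            a = np.diff(z, axis=ax)
            pair_ok = np.isfinite(a)
            if pair_ok.sum() < 2:
                continue
            dvar = np.nanvar(a)
            rho = 1.0 - dvar / 2.0
            if rho <= 0:
                fwhm[i, ax] = 0.0
            else:
                fwhm[i, ax] = vox[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log(rho))
    return np.nanmean(fwhm, axis=0)


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm,
    voxel_p: float,
    corrected_p: float = 0.05,
    n_iter: int = 1000,
    connectivity: int = 26,
    seed: int = 0,
    voxel_mm=3.0,
) -> int:
    """Minimum cluster extent k at corrected p, by smooth-noise simulation.

    Each iteration draws iid Gaussian noise on the bounding grid, smooths it
    to ``fwhm_mm``, standardizes within the mask, applies the two-tailed
    voxel threshold, and records the largest suprathreshold cluster. The
    returned k is the smallest integer with empirical P(max cluster >= k)
    <= ``corrected_p``. Deterministic given ``seed``.
    """
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must be in (0, 1)")
    if not (0 < corrected_p < 1):
        raise ValueError("corrected_p must be in (0, 1)")
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200 for a stable tail estimate")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    fwhm = float(np.nanmean(np.atleast_1d(np.asarray(fwhm_mm, dtype=float))))
    vox = float(np.mean(np.atleast_1d(voxel_mm)))
    z_crit = stats.norm.isf(voxel_p / 2.0)
    structure = connectivity_structure(connectivity)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if fwhm > 0:
            noise = smooth_gaussian(noise, fwhm_mm=fwhm, voxel_mm=vox)
        vals = noise[mask]
        z = (noise - vals.mean()) / vals.std()
        supra = mask & (np.abs(z) >= z_crit)
        maxima[it] = _max_cluster_size(supra, structure)
    # smallest k with P(max >= k) <= corrected_p
    ks = np.arange(maxima.max() + 2)
    exceed = np.array([(maxima >= k).mean() for k in ks])
    return int(ks[np.argmax(exceed <= corrected_p)])


@dataclass
class ClusterDecision:
    """Significance rule: voxel threshold + minimum cluster extent."""

    voxel_p: float = 0.05
    min_cluster_voxels: int = 1
    connectivity: int = 26
    corrected_p: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < 1):
            raise ValueError("voxel_p must be in (0,1)")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        connectivity_structure(self.connectivity)  # validates

    def t_critical(self, df: int) -> float:
        """Two-tailed critical t for the voxel-level p at the given df."""
        return float(stats.t.isf(self.voxel_p / 2.0, df))


def threshold_statmap(
    stat: StatResult,
    decision: ClusterDecision,
    mode: str = "t_based",
    ses_cut: float = 0.30,
):
    """Apply a voxel + cluster-extent threshold; return (binary map, table).

    Suprathreshold voxels are |t| > t_critical (``t_based``) or |d| > ses_cut
    (``ses_based``); positive and negative voxels are clustered separately;
    only clusters strictly larger than ``min_cluster_voxels`` survive. The
    cluster table lists size, sign, peak statistic and peak mm coordinates.
    """
    mask = np.asarray(stat.mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    if mode == "t_based":
        stat_map = np.nan_to_num(stat.t_map)
        cut = decision.t_critical(stat.df)
    elif mode == "ses_based":
        stat_map = np.nan_to_num(stat.ses_map)
        cut = ses_cut
    else:
        raise ValueError("mode must be 't_based' or 'ses_based'")

    structure = connectivity_structure(decision.connectivity)
    surviving = np.zeros(mask.shape, dtype=bool)
    rows = []
    cid = 0
    for sign, supra in (
        (1, mask & (stat_map > cut)),
        (-1, mask & (stat_map < -cut)),
    ):
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            sel = labels == lab
            size = int(sel.sum())
            if size <= decision.min_cluster_voxels:
                continue
            cid += 1
            surviving |= sel
            vals = np.where(sel, np.abs(stat_map), -np.inf)
            peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
            peak_mm = stat.affine @ np.array([*peak, 1.0])
            rows.append(
                {
                    "cluster_id": cid,
                    "sign": sign,
                    "n_voxels": size,
                    "peak_x_mm": peak_mm[0],
                    "peak_y_mm": peak_mm[1],
                    "peak_z_mm": peak_mm[2],
                    "peak_stat": float(stat_map[peak]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "sign",
            "n_voxels",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
            "peak_stat",
        ],
    )
    if len(table):
        table = table.sort_values("n_voxels", ascending=False).reset_index(drop=True)
    return surviving, table
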