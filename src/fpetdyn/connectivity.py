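"""Seed-based connectivity from voxel time series.

The subject-level engine is modality-agnostic: regress every voxel's
series on the mean series of a seed region (intercept, optionally a linear
drift, plus the seed covariate), keep the seed coefficient's t statistic
and map it to a z-score through the t cumulative distribution.  Applied to
global-ratio-normalised constant-infusion fPET series this yields
subject-level metabolic connectivity maps; applied to BOLD-like series it
yields ordinary seed-based functional connectivity, so the two modalities
can be compared voxel-for-voxel (dice overlap of thresholded group maps).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special, stats

from .groupglm import (
    ClusterResult,
    sign_flip_cluster_inference,
    two_sample_map_inference,
)
from .imageio import LabelImage, StatMap, TimeSeriesImage
from .preprocess import extract_roi_timeseries

__all__ = [
    "SeedModel",
    "seed_connectivity_subject",
    "t_to_z",
    "group_map",
    "dice_coefficient",
    "Z_MAX",
]

#: saturation bound for z-scores from numerically perfect fits
Z_MAX = 8.21


@dataclasses.dataclass
class SeedModel:
    """Subject-level seed regression specification."""

    seed: str
    nuisance: str = "none"        # none (intercept only) | drift (+ linear trend)
    frame_window: tuple[int, int] | None = None   # inclusive, applied upstream
    normalization: str = "global_ratio"

    def __post_init__(self) -> None:
        if self.nuisance not in ("none", "drift"):
            raise ValueError("nuisance must be 'none' or 'drift'")


def t_to_z(t: np.ndarray | float, df: float) -> np.ndarray | float:
    """Map t statistics to standard-normal z through the t CDF.

    Computed in the complementary tail for stability (z = Phi^-1(F_t(t)))
    and saturated at +-Z_MAX where the tail probability underflows.
    """
    if df is None or df <= 0:
        raise ValueError("t_to_z requires df > 0")
    t_arr = np.asarray(t, dtype=float)
    # one tail suffices by symmetry: work on |t|, restore the sign
    tail = stats.t.sf(np.abs(t_arr), df)          # P(T > |t|), stable for large |t|
    z_mag = -special.ndtri(np.maximum(tail, np.finfo(float).tiny))
    z_mag = np.minimum(z_mag, Z_MAX)
    z = np.sign(t_arr) * z_mag
    if np.isscalar(t):
        return float(z)
    return z


def seed_connectivity_subject(
    img: TimeSeriesImage,
    labels: LabelImage,
    model: SeedModel,
    *,
    subject: str = "",
) -> tuple[StatMap, StatMap]:
    """Voxel-wise seed regression for one subject: (t-map, z-map).

    The input is expected to be global-ratio normalised; the seed series is
    the mean over the seed region's voxels of the same image.
    """
    seed_ts = extract_roi_timeseries(img, labels, model.seed, subject=subject).values
    T = img.n_frames
    n_nuisance = 1 + (1 if model.nuisance == "drift" else 0)
    if T < n_nuisance + 2:
        raise ValueError("too few frames for the seed model")
    if np.std(seed_ts) <= 1e-12 * max(1.0, abs(np.mean(seed_ts))):
        raise ValueError(f"degenerate seed: {model.seed!r} series is constant")

    cols = [np.ones(T)]
    if model.nuisance == "drift":
        drift = np.arange(T, dtype=float)
        cols.append(drift - drift.mean())
    cols.append(seed_ts)
    X = np.column_stack(cols)
    p = X.shape[1]
    df = T - p

    mask = labels.brain_mask()
    Y = img.data[mask].T                              # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    q = xtx_inv[-1, -1]
    var = sigma2 * q
    # numerically perfect fits (e.g. inside the seed) saturate rather than overflow
    t_vals = np.zeros_like(var)
    ok = var > 1e-300
    t_vals[ok] = beta[-1, ok] / np.sqrt(var[ok])
    t_vals[~ok] = np.sign(beta[-1, ~ok]) * np.inf

    z_vals = np.where(
        np.isfinite(t_vals), t_to_z(np.nan_to_num(t_vals, posinf=0, neginf=0), df), 0.0
    )
    z_vals = np.where(np.isposinf(t_vals), Z_MAX, z_vals)
    z_vals = np.where(np.isneginf(t_vals), -Z_MAX, z_vals)

    t3d = np.full(mask.shape, np.nan)
    z3d = np.full(mask.shape, np.nan)
    t_finite = np.where(np.isfinite(t_vals), t_vals,
                        np.sign(np.nan_to_num(t_vals, posinf=1, neginf=-1)) * 1e6)
    t3d[mask] = t_finite
    z3d[mask] = z_vals
    name = f"seed {model.seed}"
    tmap = StatMap(t3d, img.affine, kind="t", df=df, contrast=name, mask=mask)
    zmap = StatMap(z3d, img.affine, kind="z", df=None, contrast=name, mask=mask)
    return tmap, zmap


def group_map(
    contrast_maps: list[StatMap],
    *,
    test: str = "one_sample",
    mask: LabelImage | np.ndarray | None = None,
    groups: np.ndarray | None = None,
    cf_threshold_p: float = 0.001,
    n_perm: int = 1000,
    extent_min: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[StatMap, ClusterResult]:
    """Group-level inference over subject z-maps.

    ``one_sample``: voxel-wise one-sample t with sign-flip max-extent
    permutation null.  ``two_sample``: two-group comparison of the maps via
    group-label permutation (groups array required, labels 'A'/'B' or any
    two values; first unique value is tested > second).
    """
    if len(contrast_maps) < 3:
        raise ValueError("need at least 3 maps")
    shape = contrast_maps[0].data.shape
    affine = contrast_maps[0].affine
    for m in contrast_maps:
        if m.data.shape != shape:
            raise ValueError("grid mismatch between subject maps")
    if mask is None:
        analysis_mask = np.all([np.isfinite(m.data) for m in contrast_maps], axis=0)
    elif isinstance(mask, LabelImage):
        analysis_mask = mask.brain_mask()
    else:
        analysis_mask = np.asarray(mask, dtype=bool)
    data = np.stack([np.nan_to_num(m.data, nan=0.0)[analysis_mask] for m in contrast_maps])

    if test == "one_sample":
        return sign_flip_cluster_inference(
            data, analysis_mask, affine,
            cf_threshold_p=cf_threshold_p, n_perm=n_perm,
            extent_min=extent_min, alpha=alpha, seed=seed,
        )
    if test != "two_sample":
        raise ValueError("test must be 'one_sample' or 'two_sample'")
    if groups is None:
        raise ValueError("two_sample test requires group labels")
    groups = np.asarray([str(g) for g in groups])
    uniq = list(dict.fromkeys(groups.tolist()))
    if len(uniq) != 2:
        raise ValueError("two_sample test requires exactly two groups")
    return two_sample_map_inference(
        data, groups, analysis_mask, affine,
        group_a=uniq[0], group_b=uniq[1],
        cf_threshold_p=cf_threshold_p, n_perm=n_perm,
        extent_min=extent_min, alpha=alpha, seed=seed,
    )


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A^B| / (|A|+|B|) of two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / (na + nb)
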