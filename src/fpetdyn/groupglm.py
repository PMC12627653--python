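"""Subject-by-time voxel-wise group comparison.

A mass-univariate GLM over subject-frame observations with a flexible
factorial design — one indicator column per subject, one per frame index,
and optionally a mean-centred global-uptake covariate (ANCOVA
normalisation).  The design is rank-deficient by construction (both factor
blocks carry an intercept); estimation uses the Moore-Penrose
pseudoinverse with an explicit estimability check on every contrast, which
makes the SPM-style factorial behaviour testable.

Inference on group contrasts is cluster-level family-wise-error control by
permutation with the subject as the exchangeable unit: the factorial fit
is collapsed to per-subject effect maps (subject coefficients,
ANCOVA-adjusted), the observed statistic is the voxel-wise pooled
two-sample t over those maps, and the null distribution of the maximum
suprathreshold cluster extent is built by relabelling subjects' groups
(two-sample) or sign-flipping per-subject maps (one-sample), with
exhaustive enumeration whenever the relabelling space fits the budget.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imageio import StatMap, SubjectTable, TimeSeriesImage

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "ClusterResult",
    "build_flexible_factorial",
    "stack_observations",
    "fit_glm",
    "contrast_t",
    "fit_glm_contrast",
    "cluster_inference_permutation",
    "two_sample_map_inference",
    "sign_flip_cluster_inference",
    "subject_effect_maps",
    "extract_clusters",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DesignMatrix:
    """Flexible-factorial design over subject-frame observations.

    Rows are ordered subject-major: all frames of subject 0, then subject 1,
    ...  Column blocks: subject indicators, frame indicators, optional
    centred global covariate.
    """

    X: np.ndarray
    subjects: list[str]
    groups: np.ndarray          # per-subject group label, aligned with `subjects`
    n_frames: int
    subject_cols: np.ndarray    # column index per subject
    time_cols: np.ndarray
    global_col: int | None
    rank: int

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def row_index(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": np.repeat(self.subjects, self.n_frames),
                "frame": np.tile(np.arange(self.n_frames), len(self.subjects)),
            }
        )

    def group_contrast(
        self, group_a: str = "HC", group_b: str = "PD", groups: np.ndarray | None = None
    ) -> np.ndarray:
        """Contrast vector testing group_a > group_b on subject effects.

        Weights +1/n_a on group_a subject columns and -1/n_b on group_b
        columns; optionally evaluated under a permuted per-subject group
        labelling.
        """
        g = self.groups if groups is None else np.asarray(groups)
        n_a = int(np.sum(g == group_a))
        n_b = int(np.sum(g == group_b))
        if n_a == 0 or n_b == 0:
            raise ValueError(f"need both groups {group_a!r} and {group_b!r}")
        c = np.zeros(self.X.shape[1])
        c[self.subject_cols[g == group_a]] = 1.0 / n_a
        c[self.subject_cols[g == group_b]] = -1.0 / n_b
        return c

    def is_estimable(self, c: np.ndarray, tol: float = 1e-8) -> bool:
        """c is estimable iff it lies in the row space of X (c' = c'X+X)."""
        pinvX = np.linalg.pinv(self.X)
        proj = (pinvX @ self.X).T @ c
        return bool(np.linalg.norm(proj - c) <= tol * max(1.0, np.linalg.norm(c)))


def build_flexible_factorial(
    table: SubjectTable,
    n_frames: int,
    globals_: np.ndarray | None = None,
) -> DesignMatrix:
    """Subject + Time factorial design, optional ANCOVA global covariate.

    ``globals_`` is the per-observation global mean series (subject-major,
    length n_subjects * n_frames); it is mean-centred before inclusion.
    """
    subjects = table.subjects
    groups = np.asarray([str(g) for g in table.groups])
    S = len(subjects)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    N = S * n_frames
    cols = S + n_frames + (1 if globals_ is not None else 0)
    X = np.zeros((N, cols))
    subject_cols = np.arange(S)
    time_cols = S + np.arange(n_frames)
    for s in range(S):
        rows = slice(s * n_frames, (s + 1) * n_frames)
        X[rows, s] = 1.0
        X[rows, time_cols] = np.eye(n_frames)
    global_col = None
    if globals_ is not None:
        globals_ = np.asarray(globals_, dtype=float).ravel()
        if globals_.size != N:
            raise ValueError(
                f"global covariate has {globals_.size} values; expected "
                f"{S} subjects x {n_frames} frames = {N} (a subject is missing frames?)"
            )
        global_col = cols - 1
        X[:, global_col] = globals_ - globals_.mean()
    rank = int(np.linalg.matrix_rank(X))
    return DesignMatrix(
        X=X, subjects=subjects, groups=groups, n_frames=n_frames,
        subject_cols=subject_cols, time_cols=time_cols,
        global_col=global_col, rank=rank,
    )


def stack_observations(
    images: list[TimeSeriesImage], mask: np.ndarray
) -> np.ndarray:
    """Stack subject image series into an observations-by-voxels matrix.

    Rows are subject-major frames (matching :func:`build_flexible_factorial`),
    columns the in-mask voxels in C order.
    """
    blocks = []
    for img in images:
        if img.data.shape[:3] != mask.shape:
            raise ValueError("image grid does not match mask")
        blocks.append(img.data[mask].T)   # (T, V)
    return np.concatenate(blocks, axis=0)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GLMFit:
    """Pseudoinverse least-squares fit of Y = X beta + eps, many voxels."""

    beta: np.ndarray       # (P, V)
    sigma2: np.ndarray     # (V,)
    df: int
    rank: int
    pinvX: np.ndarray
    X: np.ndarray
    scale: np.ndarray = None   # per-voxel mean square of Y (degeneracy reference)

    def covariance_factor(self, c: np.ndarray) -> float:
        """c'(X'X)^- c with the Moore-Penrose generalised inverse."""
        v = self.pinvX.T @ c
        return float(v @ v)


def fit_glm(Y: np.ndarray, design: DesignMatrix) -> GLMFit:
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != design.n_rows:
        raise ValueError("row count of Y does not match the design")
    df = design.n_rows - design.rank
    if df <= 0:
        raise ValueError("non-positive error degrees of freedom")
    pinvX = np.linalg.pinv(design.X)
    beta = pinvX @ Y
    resid = Y - design.X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    return GLMFit(beta=beta, sigma2=rss / df, df=df, rank=design.rank,
                  pinvX=pinvX, X=design.X,
                  scale=np.einsum("ij,ij->j", Y, Y) / Y.shape[0])


def contrast_t(fit: GLMFit, c: np.ndarray) -> np.ndarray:
    """Per-voxel t statistic for contrast c.

    Voxels the model fits perfectly (residual variance at rounding level
    relative to the data scale) report t = 0 when the contrast estimate is
    also at rounding level — a noise-free no-effect voxel — rather than
    the ratio of two rounding errors.
    """
    q = fit.covariance_factor(c)
    num = c @ fit.beta
    var = fit.sigma2 * q
    scale = fit.scale if fit.scale is not None else np.ones_like(var)
    degenerate = fit.sigma2 <= 1e-24 * np.maximum(scale, 1e-300)
    t = np.zeros_like(num)
    ok = (var > 0) & ~degenerate
    t[ok] = num[ok] / np.sqrt(var[ok])
    big = degenerate & (np.abs(num) > 1e-8 * np.sqrt(np.maximum(scale * q, 1e-300)))
    t[big] = np.sign(num[big]) * 1e6
    return t


def fit_glm_contrast(
    Y: np.ndarray,
    design: DesignMatrix,
    c: np.ndarray,
    *,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    contrast_name: str = "",
) -> StatMap | np.ndarray:
    """Fit the factorial GLM and return the contrast t-map.

    With ``mask``/``affine`` given, returns a :class:`StatMap` (NaN outside
    the mask); otherwise the raw per-voxel t vector.
    """
    if not design.is_estimable(c):
        raise ValueError("contrast is not estimable under this design")
    fit = fit_glm(Y, design)
    t = contrast_t(fit, c)
    if mask is None:
        return t
    vol = np.full(mask.shape, np.nan)
    vol[mask] = t
    return StatMap(vol, affine if affine is not None else np.eye(4),
                   kind="t", df=fit.df, contrast=contrast_name, mask=mask)


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterResult:
    """Suprathreshold clusters with permutation cluster-level FWE p-values."""

    table: pd.DataFrame          # cluster_id, extent, peak_i/j/k, peak_x/y/z, peak_stat, p_fwe, retained
    label_map: np.ndarray        # 3D int array, 0 = background
    threshold: float
    n_perm: int
    exhaustive: bool

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table.retained]

    def retained_mask(self) -> np.ndarray:
        keep = set(self.retained.cluster_id.tolist())
        out = np.isin(self.label_map, list(keep)) if keep else np.zeros_like(self.label_map, bool)
        return out


def extract_clusters(stat3d: np.ndarray, mask: np.ndarray, threshold: float):
    """26-connected suprathreshold components; returns (label_map, extents)."""
    supra = np.zeros(mask.shape, dtype=bool)
    vals = np.where(np.isfinite(stat3d), stat3d, -np.inf)
    supra[mask] = vals[mask] > threshold
    label_map, n = ndimage.label(supra, structure=_CONNECTIVITY_26)
    extents = ndimage.sum_labels(supra, label_map, index=np.arange(1, n + 1)).astype(int)
    return label_map, extents


def _max_extent(t_vec: np.ndarray, mask: np.ndarray, threshold: float,
                scratch: np.ndarray) -> int:
    scratch.fill(False)
    scratch[mask] = t_vec > threshold
    if not scratch.any():
        return 0
    label_map, n = ndimage.label(scratch, structure=_CONNECTIVITY_26)
    if n == 0:
        return 0
    return int(ndimage.sum_labels(scratch, label_map, index=np.arange(1, n + 1)).max())


def _cluster_table(
    t3d: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    threshold: float,
    null_max_extents: np.ndarray,
    m_effective: int,
    extent_min: int,
    alpha: float,
    exhaustive: bool,
) -> ClusterResult:
    label_map, extents = extract_clusters(t3d, mask, threshold)
    rows = []
    for cid, extent in enumerate(extents, start=1):
        in_cluster = label_map == cid
        vals = np.where(in_cluster, np.nan_to_num(t3d, nan=-np.inf), -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
        peak_mm = (affine @ np.array([*peak, 1.0]))[:3]
        n_ge = int(np.sum(null_max_extents >= extent))
        p = (1 + n_ge) / (m_effective + 1)
        rows.append(
            {
                "cluster_id": cid,
                "extent": int(extent),
                "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2],
                "peak_x_mm": peak_mm[0], "peak_y_mm": peak_mm[1], "peak_z_mm": peak_mm[2],
                "peak_stat": float(t3d[peak]),
                "p_fwe": p,
                "retained": bool(p <= alpha and extent > extent_min),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "extent", "peak_i", "peak_j", "peak_k",
                 "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat", "p_fwe", "retained"],
    )
    return ClusterResult(table=table, label_map=label_map, threshold=threshold,
                         n_perm=m_effective, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

_T_GUARD = 1e6


def _guarded_ratio(num: np.ndarray, se: np.ndarray) -> np.ndarray:
    """t = num/se with zero-variance voxels mapped to a guarded maximum.

    A zero standard error with a non-negligible numerator (e.g. identical
    maps across subjects) reports +-1e6 rather than infinity; a zero
    numerator reports 0.
    """
    num = np.asarray(num, float)
    t = np.zeros_like(num)
    ok = se > 0
    t[ok] = num[ok] / se[ok]
    degenerate = ~ok & (np.abs(num) > 1e-12 * max(1.0, float(np.abs(num).max(initial=0.0))))
    t[degenerate] = np.sign(num[degenerate]) * _T_GUARD
    return t


def subject_effect_maps(fit: GLMFit, design: DesignMatrix) -> np.ndarray:
    """Per-subject effect maps (subjects x voxels) from the factorial fit.

    Individual subject coefficients of the over-parameterised design are
    only defined up to a shared offset; any sum-zero contrast between them
    is unique, so the maps are centred on their grand mean, which leaves
    every between-subject comparison invariant.
    """
    B = fit.beta[design.subject_cols, :]
    return B - B.mean(axis=0, keepdims=True)


def cluster_inference_permutation(
    Y: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray,
    affine: np.ndarray,
    *,
    group_a: str = "HC",
    group_b: str = "PD",
    cf_threshold_p: float = 0.001,
    n_perm: int = 1000,
    extent_min: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[StatMap, ClusterResult]:
    """Two-sample (group-relabelling) cluster-level FWE inference.

    The factorial GLM is fitted once; each subject's voxel-wise effect map
    (its subject coefficient, ANCOVA-adjusted and time-effect-corrected)
    is the exchangeable unit.  The group comparison is the voxel-wise
    pooled two-sample t over those maps, so the permutation denominator
    reflects between-subject variability and relabelling subjects is a
    valid (and under strong effects non-degenerate) permutation scheme.

    One-sided: tests ``group_a > group_b``; run with the groups swapped
    for the opposite direction.  Cluster-forming threshold is the upper
    ``cf_threshold_p`` t-quantile at the map's df; FWE p-values come from
    the permutation null of the maximum cluster extent with conservative
    (>=) tie handling.  Clusters are retained when ``p <= alpha`` and
    ``extent > extent_min``.
    """
    c_obs = design.group_contrast(group_a, group_b)
    if not design.is_estimable(c_obs):
        raise ValueError("group contrast is not estimable under this design")
    fit = fit_glm(Y, design)
    maps = subject_effect_maps(fit, design)
    return two_sample_map_inference(
        maps, design.groups, mask, affine,
        group_a=group_a, group_b=group_b,
        cf_threshold_p=cf_threshold_p, n_perm=n_perm,
        extent_min=extent_min, alpha=alpha, seed=seed,
    )


def two_sample_map_inference(
    maps: np.ndarray,
    groups: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    *,
    group_a: str,
    group_b: str,
    cf_threshold_p: float = 0.001,
    n_perm: int = 1000,
    extent_min: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[StatMap, "ClusterResult"]:
    """Two-sample cluster inference on per-subject maps (one map each).

    Observed statistic: voxel-wise pooled two-sample t (group_a > group_b);
    the max-extent null relabels subjects' groups, exhaustively when the
    number of distinct relabellings fits the permutation budget.
    """
    maps = np.asarray(maps, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    S, V = maps.shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_a = int(np.sum(groups == group_a))
    n_b = int(np.sum(groups == group_b))
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 maps per group")
    if n_a + n_b != S:
        raise ValueError("groups must partition the maps")
    df = S - 2
    threshold = float(stats.t.isf(cf_threshold_p, df))
    total_sum = maps.sum(axis=0)
    total_ssq = np.einsum("ij,ij->j", maps, maps)
    scale = 1.0 / n_a + 1.0 / n_b

    def t_of(a_members: np.ndarray) -> np.ndarray:
        s_a = maps[a_members].sum(axis=0)
        m_a = s_a / n_a
        m_b = (total_sum - s_a) / n_b
        ss_within = total_ssq - n_a * m_a**2 - n_b * m_b**2
        s2 = np.maximum(ss_within, 0.0) / df
        se = np.sqrt(s2 * scale)
        return _guarded_ratio(m_a - m_b, se)

    obs_members = np.flatnonzero(groups == group_a)
    t_obs = t_of(obs_members)

    total = math.comb(S, n_a)
    exhaustive = total - 1 <= n_perm
    if exhaustive:
        logger.info("only %d distinct relabellings; exhaustive enumeration", total)
        observed = frozenset(obs_members.tolist())
        subsets = [np.array(c) for c in combinations(range(S), n_a)
                   if frozenset(c) != observed]
    else:
        rng = np.random.default_rng(seed)
        subsets = [rng.permutation(S)[:n_a] for _ in range(n_perm)]

    scratch = np.zeros(mask.shape, dtype=bool)
    null_max = np.empty(len(subsets), dtype=int)
    for j, members in enumerate(subsets):
        null_max[j] = _max_extent(t_of(members), mask, threshold, scratch)

    t3d = np.full(mask.shape, np.nan)
    t3d[mask] = t_obs
    tmap = StatMap(t3d, affine, kind="t", df=df,
                   contrast=f"{group_a} > {group_b}", mask=mask)
    result = _cluster_table(
        t3d, mask, affine, threshold, null_max, len(subsets),
        extent_min, alpha, exhaustive,
    )
    return tmap, result


def sign_flip_cluster_inference(
    maps: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    *,
    cf_threshold_p: float = 0.001,
    n_perm: int = 1000,
    extent_min: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[StatMap, ClusterResult]:
    """One-sample cluster inference by sign-flipping per-subject maps.

    ``maps`` is (subjects, voxels) over the in-mask voxels.  The observed
    statistic is the voxel-wise one-sample t (positive direction); the null
    maximum-extent distribution flips each subject's map by +-1, exhausting
    all 2^S patterns when that is within the permutation budget.
    """
    maps = np.asarray(maps, dtype=float)
    S, V = maps.shape
    if S < 3:
        raise ValueError("need at least 3 subject maps")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    df = S - 1
    threshold = float(stats.t.isf(cf_threshold_p, df))
    ss = np.einsum("ij,ij->j", maps, maps)

    def t_of(signs: np.ndarray) -> np.ndarray:
        m = signs @ maps / S
        var = (ss - S * m**2) / df
        se = np.sqrt(np.maximum(var, 0.0) / S)
        return _guarded_ratio(m, se)

    t_obs = t_of(np.ones(S))

    total = 2**S
    exhaustive = total - 1 <= n_perm
    if exhaustive:
        logger.info("only %d sign patterns; exhaustive enumeration", total)
        patterns = [np.array(p, dtype=float) * 2 - 1 for p in product((0, 1), repeat=S)]
        patterns = [p for p in patterns if not np.all(p == 1)]
    else:
        rng = np.random.default_rng(seed)
        patterns = list(rng.choice([-1.0, 1.0], size=(n_perm, S)))

    scratch = np.zeros(mask.shape, dtype=bool)
    null_max = np.empty(len(patterns), dtype=int)
    for j, signs in enumerate(patterns):
        null_max[j] = _max_extent(t_of(signs), mask, threshold, scratch)

    t3d = np.full(mask.shape, np.nan)
    t3d[mask] = t_obs
    tmap = StatMap(t3d, affine, kind="t", df=df, contrast="one-sample > 0", mask=mask)
    result = _cluster_table(
        t3d, mask, affine, threshold, null_max, len(patterns),
        extent_min, alpha, exhaustive,
    )
    return tmap, result
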