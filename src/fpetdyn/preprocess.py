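"""Frame windowing, smoothing, normalisation, and ROI extraction.

The standard constant-infusion pipeline feeding every analysis: keep the
late frames (low early-frame activity), smooth each frame with a Gaussian
kernel, remove the shared accumulation trend either by dividing each frame
by its in-mask global mean (ratio normalisation) or by handing the global
series to the GLM as an ANCOVA covariate, and extract per-region mean
uptake series.

Conventions: frame windows are inclusive ``[first, last]`` and 0-based;
smoothing uses reflect boundaries; the global mean is the mean over the
supplied grey-matter mask (explicit and testable, rather than an
intensity-heuristic brain mask).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .imageio import LabelImage, TimeSeriesImage

__all__ = [
    "RoiTimeSeries",
    "select_frames",
    "smooth_gaussian",
    "global_mean_series",
    "normalize_global_ratio",
    "compute_suv",
    "extract_roi_timeseries",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
_GLOBAL_TOL = 1e-9


@dataclasses.dataclass
class RoiTimeSeries:
    """Per-frame mean uptake of one region for one subject."""

    subject: str
    region: str
    values: np.ndarray
    normalization: str = "raw"   # raw | global_ratio | suv

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ROI series must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ROI series must be finite")


def select_frames(img: TimeSeriesImage, first: int, last: int) -> TimeSeriesImage:
    """Inclusive frame window [first, last]; timing metadata shifted."""
    T = img.n_frames
    if not (0 <= first <= last < T):
        raise IndexError(
            f"frame window [{first}, {last}] out of range for T={T} "
            "(window is inclusive and 0-based)"
        )
    data = img.data[..., first : last + 1]
    if data.shape[3] == 1:
        # single-frame static mean is a valid degenerate window; keep 4D
        data = data.copy()
    onset = img.frame_onset_s + first * img.frame_duration_s
    return TimeSeriesImage(data, img.affine, img.frame_duration_s, onset, img.modality)


def smooth_gaussian(img: TimeSeriesImage, fwhm_mm: float) -> TimeSeriesImage:
    """Per-frame separable Gaussian smoothing with FWHM given in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return TimeSeriesImage(
            img.data.copy(), img.affine, img.frame_duration_s, img.frame_onset_s, img.modality
        )
    sigmas = tuple(
        (fwhm_mm / v) / _FWHM_TO_SIGMA for v in img.voxel_sizes_mm()
    ) + (0.0,)
    data = gaussian_filter(img.data, sigma=sigmas, mode="reflect")
    return TimeSeriesImage(data, img.affine, img.frame_duration_s, img.frame_onset_s, img.modality)


def global_mean_series(img: TimeSeriesImage, mask: LabelImage) -> np.ndarray:
    """g(t): mean over in-mask voxels at each frame."""
    m = mask.brain_mask()
    if m.shape != img.data.shape[:3]:
        raise ValueError("mask shape does not match image grid")
    if not m.any():
        raise ValueError("empty mask")
    return img.data[m].mean(axis=0)


def normalize_global_ratio(img: TimeSeriesImage, mask: LabelImage) -> TimeSeriesImage:
    """Divide each frame by its in-mask global mean.

    The in-mask mean of every output frame is exactly 1; the shared
    accumulation trend cancels for regions tracking the global kinetics.
    """
    g = global_mean_series(img, mask)
    if np.any(g <= _GLOBAL_TOL):
        raise ValueError("degenerate global signal: non-positive global mean frame")
    data = img.data / g[None, None, None, :]
    return TimeSeriesImage(data, img.affine, img.frame_duration_s, img.frame_onset_s, img.modality)


def compute_suv(img: TimeSeriesImage, weight_kg: float, dose_MBq: float) -> TimeSeriesImage:
    """Standardised uptake values: activity scaled by weight / injected dose."""
    if not (weight_kg > 0 and dose_MBq > 0):
        raise ValueError("SUV requires positive weight and dose")
    data = img.data * (weight_kg / dose_MBq)
    return TimeSeriesImage(data, img.affine, img.frame_duration_s, img.frame_onset_s, img.modality)


def extract_roi_timeseries(
    img: TimeSeriesImage,
    labels: LabelImage,
    region: str,
    *,
    subject: str = "",
    normalization: str = "raw",
) -> RoiTimeSeries:
    """Per-frame unweighted mean over the region's voxels."""
    if labels.labels.shape != img.data.shape[:3]:
        raise ValueError("label image does not match image grid")
    mask = labels.region_mask(region)
    values = img.data[mask].mean(axis=0)
    return RoiTimeSeries(subject=subject, region=region, values=values, normalization=normalization)
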