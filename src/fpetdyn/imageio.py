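"""On-disk artefacts: NIfTI-1 images with JSON timing sidecars, TSV tables.

All images are written as float32 NIfTI-1 (labels as int16) with a JSON
sidecar next to the image (same stem, ``.json``) that is the authoritative
record of frame timing, modality and — for statistic maps — the statistic
kind and degrees of freedom.  NIfTI headers carry the frame duration in
``pixdim[4]`` as a fallback for files produced elsewhere.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesImage",
    "LabelImage",
    "StatMap",
    "SubjectTable",
    "read_timeseries_image",
    "write_timeseries_image",
    "read_label_image",
    "write_label_image",
    "read_stat_map",
    "write_stat_map",
    "load_subject_table",
    "write_subject_table",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


@dataclasses.dataclass
class TimeSeriesImage:
    """A 4D voxel time series (X, Y, Z, T) with geometry and frame timing.

    Carries both constant-infusion fPET series (monotonically accumulating
    tracer signal) and BOLD-like series; ``modality`` records which.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_duration_s: float
    frame_onset_s: float = 0.0
    modality: str = "fpet"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("not a time series: data must be 4D (X,Y,Z,T)")
        if self.data.shape[3] < 1:
            raise ValueError("not a time series: empty frame axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.frame_duration_s <= 0:
            raise ValueError("frame_duration_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if self.modality not in ("fpet", "bold"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame_midpoints_s(self) -> np.ndarray:
        """Mid-frame acquisition times in seconds."""
        t = np.arange(self.n_frames, dtype=float)
        return self.frame_onset_s + (t + 0.5) * self.frame_duration_s

    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclasses.dataclass
class LabelImage:
    """Integer-labelled 3D volume: 0 = background, named labels = ROIs/seeds."""

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels).tolist())
        for lab, name in self.names.items():
            if lab == 0:
                raise ValueError("label 0 is reserved for background")
            if lab not in present:
                raise ValueError(f"named label {lab} ({name}) absent from array")

    def label_of(self, region: str) -> int:
        for lab, name in self.names.items():
            if name == region:
                return lab
        raise KeyError(f"unknown region {region!r}")

    def region_mask(self, region: str) -> np.ndarray:
        mask = self.labels == self.label_of(region)
        if not mask.any():
            raise ValueError(f"region {region!r} is empty")
        return mask

    def brain_mask(self) -> np.ndarray:
        """All labelled voxels (grey-matter analysis mask)."""
        return self.labels > 0


@dataclasses.dataclass
class StatMap:
    """A 3D statistic map (beta, t or z) with provenance.

    ``df`` is the error degrees of freedom and is required for t-maps;
    values are meaningful only inside ``mask`` (NaN outside by convention).
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str
    df: float | None = None
    contrast: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stat map must be 3D")
        if self.kind not in ("beta", "t", "z"):
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.kind == "t":
            if self.df is None or self.df <= 0:
                raise ValueError("t-map requires df > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape mismatch")
            if not np.all(np.isfinite(self.data[self.mask])):
                raise ValueError("non-finite statistic inside mask")


class SubjectTable:
    """Per-subject clinical/demographic records backed by a DataFrame.

    Mandatory columns are ``subject`` (unique ids) and ``group``; every
    other column (age, sex, weight_kg, dose_MBq, MoCA, UPDRS hemibody item
    sums, LEDD, cognitive test scores, ...) is kept as-is and validated
    lazily by the analysis that needs it.
    """

    REQUIRED = ("subject", "group")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"subject table missing column {col!r}")
        ids = frame["subject"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject id(s): {sorted(set(dup))}")
        if frame["group"].astype(str).str.len().eq(0).any():
            raise ValueError("empty group label")
        frame["subject"] = ids
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return self.frame["subject"].tolist()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    def require(self, *columns: str, context: str = "analysis") -> pd.DataFrame:
        """Return the frame, raising if a column needed by *context* is absent."""
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise ValueError(f"{context} requires column(s) {missing}")
        return self.frame

    def row(self, subject: str) -> pd.Series:
        hit = self.frame[self.frame["subject"] == subject]
        if hit.empty:
            raise KeyError(f"unknown subject {subject!r}")
        return hit.iloc[0]


# ---------------------------------------------------------------------------
# NIfTI + sidecar IO
# ---------------------------------------------------------------------------

def read_timeseries_image(path: str | Path) -> TimeSeriesImage:
    """Read a 4D NIfTI series; timing from the JSON sidecar, header fallback."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"not a time series: {path.name} is {data.ndim}D")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        duration = float(meta["frame_duration_s"])
        onset = float(meta.get("frame_onset_s", 0.0))
        modality = str(meta.get("modality", "fpet"))
    else:
        duration = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if duration <= 0:
            raise ValueError(
                f"{path.name}: no timing sidecar and no usable frame duration in header"
            )
        onset, modality = 0.0, "fpet"
    return TimeSeriesImage(data, np.asarray(img.affine), duration, onset, modality)


def write_timeseries_image(img: TimeSeriesImage, path: str | Path) -> None:
    path = Path(path)
    header = nib.Nifti1Header()
    header.set_xyzt_units("mm", "sec")
    nii = nib.Nifti1Image(img.data.astype(np.float32), img.affine, header)
    zooms = list(nii.header.get_zooms())
    zooms[3] = img.frame_duration_s
    nii.header.set_zooms(zooms)
    nib.save(nii, str(path))
    meta = {
        "frame_duration_s": img.frame_duration_s,
        "frame_onset_s": img.frame_onset_s,
        "modality": img.modality,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_label_image(path: str | Path) -> LabelImage:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    labels = np.rint(labels).astype(np.int32)
    names: dict[int, str] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = {int(k): v for k, v in meta.get("names", {}).items()}
    return LabelImage(labels, np.asarray(img.affine), names)


def write_label_image(labels: LabelImage, path: str | Path) -> None:
    path = Path(path)
    nii = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    nib.save(nii, str(path))
    meta = {"names": {str(k): v for k, v in sorted(labels.names.items())}}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_stat_map(smap: StatMap, path: str | Path) -> None:
    """NIfTI-1 map plus a JSON sidecar recording kind/df/contrast."""
    path = Path(path)
    nii = nib.Nifti1Image(smap.data.astype(np.float32), smap.affine)
    nib.save(nii, str(path))
    meta = {
        "kind": smap.kind,
        "df": smap.df,
        "contrast": smap.contrast,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_stat_map(path: str | Path) -> StatMap:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = _sidecar_path(path)
    meta: Mapping = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return StatMap(
        np.asarray(img.dataobj, dtype=float),
        np.asarray(img.affine),
        kind=meta.get("kind", "t"),
        df=meta.get("df"),
        contrast=meta.get("contrast", ""),
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def load_subject_table(path: str | Path) -> SubjectTable:
    """Load a tab-separated subject table (header row required)."""
    frame = pd.read_csv(path, sep="\t")
    return SubjectTable(frame)


def write_subject_table(table: SubjectTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
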