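"""Synthetic constant-infusion fPET cohorts with known ground truth.

The generator emulates the statistical structure a constant-infusion FDG
study rests on, at desk scale:

* monotone tracer accumulation — each voxel rises linearly in time with a
  region-specific slope ``b_r`` (the shared kinetic shape that global-mean
  normalisation removes);
* planted hypo-/hyper-metabolism — group multipliers ``gamma[r, g]`` scale
  the slope (substantia nigra reduced, motor cortex increased in the
  patient group by default);
* planted metabolic connectivity — smooth latent signals ``L_k(t)`` shared
  between the regions of a network (striato-nigro-thalamic, default-mode)
  with coupling weights ``lambda[r, k]``; every region additionally owns a
  private latent so that its fluctuations are never degenerate;
* planted glucose-dynamics differences — a per-region, per-group
  fluctuation scale ``nu[r, g]`` (motor cortex elevated in patients) with
  per-subject lognormal scatter, the basis of coefficient-of-variation
  group differences;
* additive i.i.d. Gaussian measurement noise;
* a clinical table whose cognition scores decrease with the subject's
  motor-cortex fluctuation scale and whose UPDRS hemibody asymmetry is
  tied to the left/right substantia-nigra slope ratio.

Voxel ``v`` in region ``r`` of subject ``s`` (group ``g``) follows

    y_v(t) = scale_s * [ gamma[r,g,s] * b_r * t
                         + nu[r,g,s] * ( sum_k lambda[r,k] L_{k,s}(t)
                                         + w_priv * L_{r,s}(t) ) ] + eps

with ``t`` the mid-frame time in minutes, ``L`` smooth zero-mean
unit-variance series and ``eps ~ N(0, sigma_eps^2)`` i.i.d.  Identical
seeds give bit-identical output; each subject owns RNG streams derived
from the master seed, so cohorts are extensible without changing earlier
subjects.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .imageio import LabelImage, SubjectTable, TimeSeriesImage

__all__ = [
    "Region",
    "LatentSpec",
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_bold_series",
    "emit_truth",
    "build_atlas",
    "default_norm_table",
    "STRIATO_NIGRO_THALAMIC",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: regions forming the planted subcortical network (masked analyses)
STRIATO_NIGRO_THALAMIC = (
    "SN_left",
    "SN_right",
    "putamen_left",
    "putamen_right",
    "thalamus_left",
    "thalamus_right",
)

_COGNITIVE_TESTS = ("moca", "wmsr", "panda", "rwt")

# per test: {age band -> (norm mean, norm SD)}; decade bands
_NORMS = {
    "moca": {(50, 59): (27.5, 2.2), (60, 69): (27.0, 2.2), (70, 79): (26.5, 2.2)},
    "wmsr": {(50, 59): (102.0, 15.0), (60, 69): (100.0, 15.0), (70, 79): (98.0, 15.0)},
    "panda": {(50, 59): (26.0, 3.0), (60, 69): (25.0, 3.0), (70, 79): (24.0, 3.0)},
    "rwt": {(50, 59): (32.0, 8.0), (60, 69): (30.0, 8.0), (70, 79): (28.0, 8.0)},
}


@dataclasses.dataclass(frozen=True)
class Region:
    """A spherical ROI on the phantom grid (centre voxel, radius in voxels)."""

    name: str
    center: tuple[int, int, int]
    radius: float


@dataclasses.dataclass(frozen=True)
class LatentSpec:
    """A shared latent signal with per-region coupling weights."""

    name: str
    weights: dict[str, float]


def _default_regions() -> tuple[Region, ...]:
    return (
        Region("SN_left", (8, 8, 5), 2.0),
        Region("SN_right", (15, 8, 5), 2.0),
        Region("putamen_left", (5, 13, 8), 2.0),
        Region("putamen_right", (18, 13, 8), 2.0),
        Region("caudate_left", (9, 16, 11), 2.0),
        Region("caudate_right", (14, 16, 11), 2.0),
        Region("thalamus_left", (9, 11, 14), 2.0),
        Region("thalamus_right", (14, 11, 14), 2.0),
        Region("motor_cortex", (11, 6, 17), 2.5),
        Region("precuneus", (11, 18, 15), 2.0),
        Region("occipital", (11, 20, 8), 2.0),
        Region("angular_left", (5, 18, 13), 2.0),
        Region("angular_right", (18, 18, 13), 2.0),
    )


def _default_latents() -> tuple[LatentSpec, ...]:
    return (
        LatentSpec(
            "striato_nigro_thalamic",
            {
                "SN_left": 1.0,
                "SN_right": 1.0,
                "putamen_left": 0.9,
                "putamen_right": 0.9,
                "thalamus_left": 0.8,
                "thalamus_right": 0.8,
            },
        ),
        LatentSpec(
            "default_mode",
            {"precuneus": 1.0, "angular_left": 0.9, "angular_right": 0.9},
        ),
    )


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the acquisition the analyses assume (90 one-minute
    frames; 13 controls vs 14 patients) on a 24x24x20 grid with 4 mm
    voxels, with moderate planted regional effects: a 7% slope reduction
    in the substantia nigra and a 7% increase in the motor cortex in the
    patient group, and a motor-cortex fluctuation scale 1.8x higher in
    patients.
    """

    shape: tuple[int, int, int] = (24, 24, 20)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_frames: int = 90
    frame_duration_s: float = 60.0
    regions: tuple[Region, ...] = dataclasses.field(default_factory=_default_regions)
    latents: tuple[LatentSpec, ...] = dataclasses.field(default_factory=_default_latents)
    baseline_slope: float = 1.0          # intensity per minute, all grey matter
    background_slope: float = 0.1        # outside the brain ellipsoid
    group_slope_multipliers: dict = dataclasses.field(
        default_factory=lambda: {
            ("SN_left", "PD"): 0.93,
            ("SN_right", "PD"): 0.93,
            ("motor_cortex", "PD"): 1.07,
        }
    )
    # per (region, group) multipliers on fluct_scale_base
    fluct_scale: dict = dataclasses.field(
        default_factory=lambda: {("motor_cortex", "PD"): 1.8}
    )
    fluct_scale_base: float = 1.4
    fluct_subject_sd: float = 0.15       # lognormal sigma of per-subject nu scatter
    private_latent_weight: float = 0.35
    latent_fwhm_frames: float = 3.0
    noise_sd: float = 1.0
    subject_scale_sd: float = 0.05       # lognormal sigma of whole-image scale
    n_hc: int = 13
    n_pd: int = 14
    bold_n_frames: int = 300
    bold_frame_duration_s: float = 1.0
    sn_asymmetry: float = 0.06           # left/right SN slope split in patients
    cognition_beta: float = 0.6          # cognition decline per unit motor nu deviation
    cognition_noise_sd: float = 0.8
    test_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.frame_duration_s <= 0:
            raise ValueError("need n_frames >= 2 and positive frame duration")
        if self.noise_sd < 0 or self.fluct_scale_base <= 0 or self.baseline_slope <= 0:
            raise ValueError("scales must be positive")
        if self.n_hc < 1 or self.n_pd < 1:
            raise ValueError("cohort sizes must be positive")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names")
        for latent in self.latents:
            unknown = set(latent.weights) - set(names)
            if unknown:
                raise ValueError(f"latent {latent.name!r} couples unknown regions {unknown}")

    # -- derived cohort layout ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.n_hc + self.n_pd

    def subject_ids(self) -> list[str]:
        return [f"hc{i+1:02d}" for i in range(self.n_hc)] + [
            f"pd{i+1:02d}" for i in range(self.n_pd)
        ]

    def group_of(self, index: int) -> str:
        return "HC" if index < self.n_hc else "PD"

    def gamma(self, region: str, group: str) -> float:
        return float(self.group_slope_multipliers.get((region, group), 1.0))

    def nu(self, region: str, group: str) -> float:
        """Fluctuation scale: base amplitude times the group multiplier."""
        return self.fluct_scale_base * float(self.fluct_scale.get((region, group), 1.0))


@dataclasses.dataclass
class GroundTruth:
    """Emitted generative truth for recovery testing.

    ``slopes`` and ``fluctuations`` are per subject x region (effective
    values including per-subject scatter and SN asymmetry, excluding the
    whole-image subject scale, which is listed separately);
    ``connectivity`` marks region pairs sharing a latent signal.
    """

    slopes: pd.DataFrame            # subject, region, slope
    fluctuations: pd.DataFrame      # subject, region, nu
    coupling: pd.DataFrame          # region, latent, weight (shared latents)
    connectivity: pd.DataFrame      # region_a, region_b, connected (bool)
    subject_scale: pd.DataFrame     # subject, scale
    asymmetry: pd.DataFrame         # subject, reduced_sn_side ("left"/"right"/"none")
    clinical_params: dict

    def connected(self, region_a: str, region_b: str) -> bool:
        hit = self.connectivity[
            (self.connectivity.region_a == region_a) & (self.connectivity.region_b == region_b)
            | (self.connectivity.region_a == region_b) & (self.connectivity.region_b == region_a)
        ]
        if hit.empty:
            raise KeyError((region_a, region_b))
        return bool(hit.iloc[0].connected)

    def to_json(self) -> str:
        payload = {
            "slopes": self.slopes.to_dict(orient="list"),
            "fluctuations": self.fluctuations.to_dict(orient="list"),
            "coupling": self.coupling.to_dict(orient="list"),
            "connectivity": self.connectivity.assign(
                connected=self.connectivity.connected.astype(bool)
            ).to_dict(orient="list"),
            "subject_scale": self.subject_scale.to_dict(orient="list"),
            "asymmetry": self.asymmetry.to_dict(orient="list"),
            "clinical_params": self.clinical_params,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def build_atlas(config: SimConfig) -> LabelImage:
    """Label image: regions 1..R, diffuse grey matter (ellipsoid) = R+1.

    Raises if any two regions overlap.
    """
    nx, ny, nz = config.shape
    labels = np.zeros(config.shape, dtype=np.int32)
    names: dict[int, str] = {}
    xx, yy, zz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    for lab, region in enumerate(config.regions, start=1):
        cx, cy, cz = region.center
        sphere = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= region.radius**2
        if not sphere.any():
            raise ValueError(f"region {region.name!r} is empty on this grid")
        if (labels[sphere] != 0).any():
            raise ValueError(f"region {region.name!r} overlaps another region")
        labels[sphere] = lab
        names[lab] = region.name
    # brain ellipsoid for unspecific grey matter
    ellipsoid = (
        ((xx - (nx - 1) / 2) / (nx * 0.42)) ** 2
        + ((yy - (ny - 1) / 2) / (ny * 0.42)) ** 2
        + ((zz - (nz - 1) / 2) / (nz * 0.44)) ** 2
    ) <= 1.0
    gm_other = ellipsoid & (labels == 0)
    lab_other = len(config.regions) + 1
    labels[gm_other] = lab_other
    names[lab_other] = "gm_other"
    affine = np.diag(list(config.voxel_size_mm) + [1.0])
    return LabelImage(labels, affine, names)


# ---------------------------------------------------------------------------
# Per-subject parameter draws (truth stream, independent of image noise)
# ---------------------------------------------------------------------------

def _norm_band(test: str, age: float) -> tuple[float, float]:
    for (lo, hi), (mean, sd) in _NORMS[test].items():
        if lo <= age <= hi:
            return mean, sd
    raise ValueError(f"age {age} outside norm bands for {test}")


def _subject_params(config: SimConfig, index: int) -> dict:
    rng = np.random.default_rng([config.seed, 11, index])
    group = config.group_of(index)
    age = float(np.clip(np.round(rng.normal(65.0, 7.0)), 51, 79))
    sex = str(rng.choice(["F", "M"]))
    weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 110.0))
    dose = float(np.clip(rng.normal(199.3, 5.3), 150.0, 250.0))
    scale = float(np.exp(rng.normal(0.0, config.subject_scale_sd)))

    nus = {
        r.name: config.nu(r.name, group) * float(np.exp(rng.normal(0.0, config.fluct_subject_sd)))
        for r in config.regions
    }
    gammas = {r.name: config.gamma(r.name, group) for r in config.regions}

    # SN lateralisation: patients get an asymmetric nigral slope split; the
    # clinically more affected hemibody is contralateral to the reduced SN
    if group == "PD" and {"SN_left", "SN_right"} <= set(gammas):
        reduced_side = str(rng.choice(["left", "right"]))
        delta = config.sn_asymmetry
        lo, hi = 1.0 - delta / 2.0, 1.0 + delta / 2.0
        if reduced_side == "left":
            gammas["SN_left"] *= lo
            gammas["SN_right"] *= hi
        else:
            gammas["SN_left"] *= hi
            gammas["SN_right"] *= lo
    else:
        reduced_side = "none"

    # motor scores: patients asymmetric, contralateral to the reduced SN
    if group == "PD":
        total = float(np.clip(rng.normal(22.0, 5.0), 8.0, 45.0))
        frac = 0.65
        affected = "right" if reduced_side == "left" else "left"
        right = total * (frac if affected == "right" else 1 - frac)
        left = total - right
        updrs_right = float(np.round(right + rng.normal(0, 0.5)))
        updrs_left = float(np.round(left + rng.normal(0, 0.5)))
        ledd = float(np.clip(rng.normal(600.0, 150.0), 100.0, 1500.0))
        duration = float(np.round(rng.uniform(3.0, 8.0), 1))
    else:
        updrs_right = float(rng.poisson(0.5))
        updrs_left = float(rng.poisson(0.5))
        ledd = 0.0
        duration = 0.0

    # cognition declines with the motor-cortex fluctuation scale (neutral
    # when the atlas has no motor cortex, e.g. reduced test configs); the
    # relative deviation keeps the clinical model invariant to the overall
    # fluctuation amplitude
    nu_motor = nus.get("motor_cortex", config.fluct_scale_base)
    cognition = -config.cognition_beta * (nu_motor / config.fluct_scale_base - 1.0) / 0.4
    cognition += float(rng.normal(0.0, config.cognition_noise_sd))
    scores = {}
    for test in _COGNITIVE_TESTS:
        mean, sd = _norm_band(test, age)
        score = mean + sd * (cognition + float(rng.normal(0.0, config.test_noise_sd)))
        if test == "moca":
            score = float(np.clip(np.round(score), 0, 30))
        scores[test] = float(np.round(score, 2))

    return {
        "group": group,
        "age": age,
        "sex": sex,
        "weight_kg": round(weight, 1),
        "dose_MBq": round(dose, 1),
        "scale": scale,
        "nus": nus,
        "gammas": gammas,
        "reduced_sn_side": reduced_side,
        "updrs_right": updrs_right,
        "updrs_left": updrs_left,
        "ledd_mg": round(ledd, 1),
        "disease_duration_y": duration,
        "cognition_z_true": cognition,
        "scores": scores,
    }


# ---------------------------------------------------------------------------
# Latents and images
# ---------------------------------------------------------------------------

def _smooth_latents(rng: np.random.Generator, n_latents: int, n_frames: int,
                    fwhm_frames: float) -> np.ndarray:
    """Gaussian-smoothed, standardised white-noise series, shape (k, T)."""
    raw = rng.standard_normal((n_latents, n_frames))
    sigma = max(fwhm_frames, 1e-9) / _FWHM_TO_SIGMA
    smooth = gaussian_filter1d(raw, sigma=sigma, axis=1, mode="reflect")
    smooth -= smooth.mean(axis=1, keepdims=True)
    sd = smooth.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return smooth / sd


def _region_fluctuation(config: SimConfig, rng: np.random.Generator,
                        n_frames: int) -> dict[str, np.ndarray]:
    """Per-region fluctuation series (unit nu): shared network + private latent."""
    shared = _smooth_latents(rng, len(config.latents), n_frames, config.latent_fwhm_frames)
    private = _smooth_latents(rng, len(config.regions), n_frames, config.latent_fwhm_frames)
    out: dict[str, np.ndarray] = {}
    for j, region in enumerate(config.regions):
        series = config.private_latent_weight * private[j]
        for k, latent in enumerate(config.latents):
            w = latent.weights.get(region.name, 0.0)
            if w:
                series = series + w * shared[k]
        out[region.name] = series
    return out


def _synthesize_image(config: SimConfig, atlas: LabelImage, params: dict,
                      rng: np.random.Generator, *, n_frames: int,
                      frame_duration_s: float, with_slope: bool,
                      modality: str) -> TimeSeriesImage:
    t_min = (np.arange(n_frames) + 0.5) * frame_duration_s / 60.0
    labels = atlas.labels
    data = np.zeros(config.shape + (n_frames,), dtype=np.float64)

    if with_slope:
        slope = np.full(config.shape, config.background_slope, dtype=np.float64)
        slope[labels > 0] = config.baseline_slope
        for lab, region in enumerate(config.regions, start=1):
            slope[labels == lab] = params["gammas"][region.name] * config.baseline_slope
        data += slope[..., None] * t_min[None, None, None, :]

    fluct = _region_fluctuation(config, rng, n_frames)
    for lab, region in enumerate(config.regions, start=1):
        series = params["nus"][region.name] * fluct[region.name]
        data[labels == lab] += series[None, :]

    data *= params["scale"]
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)
    affine = np.diag(list(config.voxel_size_mm) + [1.0])
    return TimeSeriesImage(data, affine, frame_duration_s, 0.0, modality)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimConfig,
) -> tuple[list[TimeSeriesImage], SubjectTable, LabelImage, GroundTruth]:
    """Draw the full synthetic cohort: images, clinical table, atlas, truth."""
    atlas = build_atlas(config)
    images: list[TimeSeriesImage] = []
    rows = []
    for i, sid in enumerate(config.subject_ids()):
        params = _subject_params(config, i)
        rng = np.random.default_rng([config.seed, 7, i])
        img = _synthesize_image(
            config, atlas, params, rng,
            n_frames=config.n_frames, frame_duration_s=config.frame_duration_s,
            with_slope=True, modality="fpet",
        )
        images.append(img)
        row = {
            "subject": sid,
            "group": params["group"],
            "age": params["age"],
            "sex": params["sex"],
            "weight_kg": params["weight_kg"],
            "dose_MBq": params["dose_MBq"],
            "n_frames": config.n_frames,
            "updrs3_right": params["updrs_right"],
            "updrs3_left": params["updrs_left"],
            "ledd_mg": params["ledd_mg"],
            "disease_duration_y": params["disease_duration_y"],
        }
        for test in _COGNITIVE_TESTS:
            row[test] = params["scores"][test]
        rows.append(row)
    table = SubjectTable(pd.DataFrame(rows))
    return images, table, atlas, emit_truth(config)


def generate_bold_series(config: SimConfig) -> list[TimeSeriesImage]:
    """BOLD-like companion series: same latent-coupling machinery, no
    accumulation term, 1-second frames."""
    atlas = build_atlas(config)
    images = []
    for i in range(config.n_subjects):
        params = _subject_params(config, i)
        rng = np.random.default_rng([config.seed, 13, i])
        images.append(
            _synthesize_image(
                config, atlas, params, rng,
                n_frames=config.bold_n_frames,
                frame_duration_s=config.bold_frame_duration_s,
                with_slope=False, modality="bold",
            )
        )
    return images


def emit_truth(config: SimConfig) -> GroundTruth:
    """Truth tables consistent with :func:`generate_cohort` at the same seed."""
    ids = config.subject_ids()
    slope_rows, fluct_rows, scale_rows, asym_rows = [], [], [], []
    for i, sid in enumerate(ids):
        params = _subject_params(config, i)
        scale_rows.append({"subject": sid, "scale": params["scale"]})
        asym_rows.append({"subject": sid, "reduced_sn_side": params["reduced_sn_side"]})
        for region in config.regions:
            slope_rows.append(
                {
                    "subject": sid,
                    "region": region.name,
                    "slope": params["gammas"][region.name] * config.baseline_slope,
                }
            )
            fluct_rows.append(
                {"subject": sid, "region": region.name, "nu": params["nus"][region.name]}
            )
    coupling_rows = [
        {"region": region, "latent": latent.name, "weight": w}
        for latent in config.latents
        for region, w in sorted(latent.weights.items())
    ]
    conn_rows = []
    names = [r.name for r in config.regions]
    shared = {latent.name: latent.weights for latent in config.latents}
    for a_i, a in enumerate(names):
        for b in names[a_i + 1:]:
            prod = sum(
                w.get(a, 0.0) * w.get(b, 0.0) for w in shared.values()
            )
            conn_rows.append({"region_a": a, "region_b": b, "connected": prod != 0.0})
    clinical_params = {
        "cognition_beta": config.cognition_beta,
        "cognition_noise_sd": config.cognition_noise_sd,
        "fluct_scale_base": config.fluct_scale_base,
        "sn_asymmetry": config.sn_asymmetry,
    }
    return GroundTruth(
        slopes=pd.DataFrame(slope_rows),
        fluctuations=pd.DataFrame(fluct_rows),
        coupling=pd.DataFrame(coupling_rows),
        connectivity=pd.DataFrame(conn_rows),
        subject_scale=pd.DataFrame(scale_rows),
        asymmetry=pd.DataFrame(asym_rows),
        clinical_params=clinical_params,
    )


def default_norm_table() -> pd.DataFrame:
    """Age-banded cognitive norm table matching the generator's test battery."""
    rows = []
    for test, bands in _NORMS.items():
        for (lo, hi), (mean, sd) in bands.items():
            rows.append(
                {"test": test, "age_min": lo, "age_max": hi, "mean": mean, "sd": sd}
            )
    return pd.DataFrame(rows)


def cognitive_test_names() -> Sequence[str]:
    return _COGNITIVE_TESTS
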