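"""End-to-end analysis stages over a cohort of constant-infusion series.

Each function is one pipeline stage operating on in-memory objects; the
``stage_*`` wrappers read/write the on-disk artefacts (NIfTI + TSV + JSON)
so the stages can be driven from the command line deterministically.

Default analysis parameters mirror the standard protocol: 5 mm smoothing,
the last 30 of 90 one-minute frames, ANCOVA global normalisation inside
the factorial GLM, ratio normalisation for ROI extraction, cluster-level
FWE at alpha 0.05 with a 20-voxel extent filter for the group comparison.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import clinical as _clinical
from . import dynamics as _dynamics
from .connectivity import SeedModel, group_map, seed_connectivity_subject
from .groupglm import (
    ClusterResult,
    build_flexible_factorial,
    cluster_inference_permutation,
    stack_observations,
)
from .imageio import (
    LabelImage,
    StatMap,
    SubjectTable,
    TimeSeriesImage,
    load_subject_table,
    read_label_image,
    read_timeseries_image,
    write_label_image,
    write_stat_map,
    write_subject_table,
    write_timeseries_image,
)
from .preprocess import (
    compute_suv,
    extract_roi_timeseries,
    normalize_global_ratio,
    select_frames,
    smooth_gaussian,
)
from .synthio import (
    STRIATO_NIGRO_THALAMIC,
    SimConfig,
    default_norm_table,
    generate_bold_series,
    generate_cohort,
)

__all__ = [
    "AnalysisOptions",
    "preprocess_cohort",
    "group_difference",
    "cluster_features",
    "connectivity_analysis",
    "dynamics_analysis",
    "clinical_analysis",
    "classification_analysis",
    "stage_simulate",
    "stage_preprocess",
    "stage_groupdiff",
    "stage_connectivity",
    "stage_dynamics",
    "stage_clinical",
    "stage_classify",
]


@dataclasses.dataclass
class AnalysisOptions:
    frames: tuple[int, int] = (60, 89)   # inclusive window: last 30 of 90
    fwhm_mm: float = 5.0
    cf_threshold_p: float = 0.001
    n_perm: int = 500
    extent_min: int = 20
    alpha: float = 0.05
    seed_region: str = "SN_left"
    seed: int = 0


# ---------------------------------------------------------------------------
# In-memory stages
# ---------------------------------------------------------------------------

def preprocess_cohort(
    images: list[TimeSeriesImage],
    atlas: LabelImage,
    options: AnalysisOptions,
    *,
    normalize: bool = False,
) -> list[TimeSeriesImage]:
    """Smooth, select the frame window, optionally ratio-normalise."""
    out = []
    for img in images:
        frames = options.frames if img.modality == "fpet" else (0, img.n_frames - 1)
        # windowing commutes with per-frame spatial smoothing; window first
        proc = select_frames(img, *frames)
        proc = smooth_gaussian(proc, options.fwhm_mm)
        if normalize:
            proc = normalize_global_ratio(proc, atlas)
        out.append(proc)
    return out


def group_difference(
    images: list[TimeSeriesImage],
    table: SubjectTable,
    atlas: LabelImage,
    options: AnalysisOptions,
) -> dict:
    """Subject-by-time factorial GLM with ANCOVA globals, both contrasts.

    ``images`` must already be smoothed and windowed (raw intensities; the
    global covariate does the normalisation).  Returns t-maps and cluster
    tables for HC>PD (hypometabolism in PD) and PD>HC (hypermetabolism).
    """
    mask = atlas.brain_mask()
    Y = stack_observations(images, mask)
    globals_ = np.concatenate([img.data[mask].mean(axis=0) for img in images])
    n_frames = images[0].n_frames
    design = build_flexible_factorial(table, n_frames, globals_)
    results = {}
    for key, (ga, gb) in {"hypo": ("HC", "PD"), "hyper": ("PD", "HC")}.items():
        tmap, clusters = cluster_inference_permutation(
            Y, design, mask, atlas.affine,
            group_a=ga, group_b=gb,
            cf_threshold_p=options.cf_threshold_p,
            n_perm=options.n_perm,
            extent_min=options.extent_min,
            alpha=options.alpha,
            seed=options.seed,
        )
        results[key] = {"tmap": tmap, "clusters": clusters}
    results["design_rank"] = design.rank
    return results


def cluster_features(
    images: list[TimeSeriesImage],
    table: SubjectTable,
    atlas: LabelImage,
    groupdiff: dict,
    options: AnalysisOptions,
) -> _classify.FeatureMatrix:
    """Per-subject mean normalised uptake inside each retained cluster."""
    normalized = [normalize_global_ratio(img, atlas) for img in images]
    feats: dict[str, list[float]] = {}
    kinds: dict[str, str] = {}
    for kind in ("hypo", "hyper"):
        clusters: ClusterResult = groupdiff[kind]["clusters"]
        for _, row in clusters.retained.iterrows():
            cid = int(row.cluster_id)
            voxels = clusters.label_map == cid
            name = f"{kind}_c{cid}"
            kinds[name] = kind
            feats[name] = [img.data[voxels].mean() for img in normalized]
    if not feats:
        raise ValueError("no retained clusters; nothing to classify")
    features = pd.DataFrame(feats, index=pd.Index(table.subjects, name="subject"))
    labels = pd.Series(
        (table.groups == "PD").astype(int), index=features.index, name="group"
    )
    return _classify.FeatureMatrix(features, labels, kinds)


def connectivity_analysis(
    images: list[TimeSeriesImage],
    table: SubjectTable,
    atlas: LabelImage,
    options: AnalysisOptions,
    *,
    network_mask: bool = False,
) -> dict:
    """Seed connectivity: per-subject z-maps and the one-sample group map.

    ``images`` must already be ratio-normalised and windowed.  With
    ``network_mask`` the group inference is restricted to the
    striato-nigro-thalamic labels.
    """
    model = SeedModel(seed=options.seed_region, normalization="global_ratio")
    zmaps: list[StatMap] = []
    for sid, img in zip(table.subjects, images):
        _, zmap = seed_connectivity_subject(img, atlas, model, subject=sid)
        zmaps.append(zmap)
    mask = None
    if network_mask:
        mask = np.isin(
            atlas.labels, [atlas.label_of(r) for r in STRIATO_NIGRO_THALAMIC]
        )
    group_t, clusters = group_map(
        zmaps, test="one_sample", mask=mask,
        cf_threshold_p=options.cf_threshold_p, n_perm=options.n_perm,
        extent_min=0, alpha=options.alpha, seed=options.seed,
    )
    return {"zmaps": zmaps, "group_tmap": group_t, "clusters": clusters}


def dynamics_analysis(
    images: list[TimeSeriesImage],
    table: SubjectTable,
    atlas: LabelImage,
    options: AnalysisOptions,
    *,
    regions: tuple[str, ...] = ("motor_cortex",),
    n_perm: int = 5000,
) -> dict:
    """CoV/tSNR per subject and region, group tests, clinical correlation.

    ``images`` must be ratio-normalised and windowed.
    """
    series = [
        extract_roi_timeseries(img, atlas, region, subject=sid, normalization="global_ratio")
        for sid, img in zip(table.subjects, images)
        for region in regions
    ]
    cov = _dynamics.cov_table(series)
    groups = dict(zip(table.subjects, table.groups))
    cov["group"] = cov["subject"].map(groups)
    moca = (table.frame.set_index("subject")["moca"]
            if "moca" in table.frame.columns else None)
    stats_rows = []
    for region in regions:
        sub = cov[cov.region == region]
        a = sub[sub.group == "PD"]["vc_percent"].to_numpy()
        b = sub[sub.group == "HC"]["vc_percent"].to_numpy()
        observed, p = _dynamics.permutation_group_test(
            a, b, n_perm=n_perm, seed=options.seed
        )
        row = {
            "region": region,
            "delta_vc_pd_minus_hc": observed,
            "p_permutation": p,
            "effect_size_r": _dynamics.rank_effect_size_r(a, b),
        }
        if moca is not None:
            r, p_r, n_pairs = _dynamics.correlate_with_clinical(
                sub.set_index("subject")["vc_percent"], moca)
            row.update({"clinical_r_moca": r, "clinical_p_moca": p_r,
                        "clinical_n": n_pairs})
        stats_rows.append(row)
    return {"cov_table": cov, "group_stats": pd.DataFrame(stats_rows)}


def clinical_analysis(table: SubjectTable, norms: _clinical.NormTable) -> pd.DataFrame:
    """Per-subject cognitive z-scores, MCI label, motor lateralisation."""
    from .synthio import cognitive_test_names

    tests = [t for t in cognitive_test_names() if t in table.frame.columns]
    if not tests:
        raise ValueError("subject table has no known cognitive test columns")
    rows = []
    frame = table.require("age", *tests, context="clinical scoring")
    for _, rec in frame.iterrows():
        scores = {t: rec[t] for t in tests}
        z, composite = _clinical.cognitive_z_scores(scores, float(rec["age"]), norms)
        status = _clinical.classify_mci(z)
        lat = _clinical.motor_lateralisation(
            float(rec.get("updrs3_right", np.nan)), float(rec.get("updrs3_left", np.nan))
        )
        row = {
            "subject": rec["subject"],
            "group": rec["group"],
            "cognition_z": composite,
            "cognitive_status": status,
            "motor_lateralisation": lat,
        }
        row.update({f"z_{t}": z.get(t, np.nan) for t in tests})
        rows.append(row)
    return pd.DataFrame(rows)


def classification_analysis(matrix: _classify.FeatureMatrix) -> pd.DataFrame:
    """AUC per feature subset (all / hypo / hyper clusters)."""
    rows = []
    for subset in ("all", "hypo", "hyper"):
        try:
            res = _classify.logistic_roc(matrix, subset)
        except ValueError:
            continue
        rows.append(
            {
                "subset": subset,
                "auc": res.auc,
                "n_features": len(res.coefficients),
                "separation": res.separation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-level stages (CLI surface)
# ---------------------------------------------------------------------------

def default_frame_window(n_frames: int) -> tuple[int, int]:
    """Retain the last third of the series (60..89 for the 90-frame default)."""
    first = n_frames - max(n_frames // 3, min(2, n_frames))
    return (first, n_frames - 1)


def _default_options(seed: int, **overrides) -> AnalysisOptions:
    return dataclasses.replace(AnalysisOptions(seed=seed), **overrides)


def stage_simulate(out_dir: str | Path, *, seed: int = 0, config: SimConfig | None = None,
                   with_bold: bool = False) -> Path:
    """Write per-subject NIfTI series, atlas, subjects.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config if config is not None else SimConfig(seed=seed)
    images, table, atlas, truth = generate_cohort(cfg)
    for sid, img in zip(table.subjects, images):
        write_timeseries_image(img, out / f"{sid}_fpet.nii.gz")
    if with_bold:
        for sid, img in zip(table.subjects, generate_bold_series(cfg)):
            write_timeseries_image(img, out / f"{sid}_bold.nii.gz")
    write_label_image(atlas, out / "atlas.nii.gz")
    write_subject_table(table, out / "subjects.tsv")
    (out / "truth.json").write_text(truth.to_json())
    default_norm_table().to_csv(out / "norms.tsv", sep="\t", index=False)
    return out


def _load_cohort(data_dir: Path, modality: str = "fpet"):
    table = load_subject_table(data_dir / "subjects.tsv")
    atlas = read_label_image(data_dir / "atlas.nii.gz")
    images = [
        read_timeseries_image(data_dir / f"{sid}_{modality}.nii.gz")
        for sid in table.subjects
    ]
    return images, table, atlas


def stage_preprocess(data_dir: str | Path, out_dir: str | Path, *, seed: int = 0,
                     frames: tuple[int, int] | None = None, fwhm_mm: float = 5.0,
                     norm: str = "global_ratio") -> Path:
    """Smooth + window (+ normalise) every subject; write processed NIfTIs
    and the per-subject-region extraction TSV."""
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, table, atlas = _load_cohort(data_dir)
    if frames is None:
        frames = default_frame_window(images[0].n_frames)
    options = _default_options(seed, frames=frames, fwhm_mm=fwhm_mm)
    if norm == "suv":
        frame_tbl = table.require("weight_kg", "dose_MBq", context="SUV normalisation")
        images = [
            compute_suv(img, float(rec["weight_kg"]), float(rec["dose_MBq"]))
            for img, (_, rec) in zip(images, frame_tbl.iterrows())
        ]
    processed = preprocess_cohort(images, atlas, options, normalize=(norm == "global_ratio"))
    rows = []
    region_names = [n for n in atlas.names.values() if n != "gm_other"]
    for sid, img in zip(table.subjects, processed):
        write_timeseries_image(img, out / f"{sid}_proc.nii.gz")
        for region in region_names:
            ts = extract_roi_timeseries(img, atlas, region, subject=sid, normalization=norm)
            for frame, value in enumerate(ts.values):
                rows.append({"subject": sid, "region": region, "frame": frame,
                             "value": value})
    pd.DataFrame(rows).to_csv(out / "extraction.tsv", sep="\t", index=False,
                              float_format="%.8g")
    return out


def stage_groupdiff(data_dir: str | Path, out_dir: str | Path, *, seed: int = 0,
                    n_perm: int = 500, extent_min: int = 20, alpha: float = 0.05,
                    cf_threshold_p: float = 0.001,
                    frames: tuple[int, int] | None = None) -> Path:
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, table, atlas = _load_cohort(data_dir)
    if frames is None:
        frames = default_frame_window(images[0].n_frames)
    options = _default_options(seed, n_perm=n_perm, extent_min=extent_min,
                               alpha=alpha, cf_threshold_p=cf_threshold_p,
                               frames=frames)
    windowed = preprocess_cohort(images, atlas, options, normalize=False)
    result = group_difference(windowed, table, atlas, options)
    for kind in ("hypo", "hyper"):
        write_stat_map(result[kind]["tmap"], out / f"tmap_{kind}.nii.gz")
        result[kind]["clusters"].table.to_csv(
            out / f"clusters_{kind}.tsv", sep="\t", index=False, float_format="%.8g"
        )
    # extracted per-cluster mean normalised series, for plotting/classification
    try:
        matrix = cluster_features(windowed, table, atlas, result, options)
        matrix.features.assign(group=table.groups).to_csv(
            out / "cluster_features.tsv", sep="\t", float_format="%.8g"
        )
        json.dump(matrix.feature_kind, (out / "cluster_feature_kind.json").open("w"),
                  indent=1, sort_keys=True)
    except ValueError:
        pass
    return out


def stage_connectivity(data_dir: str | Path, out_dir: str | Path, *, seed: int = 0,
                       seed_region: str = "SN_left", n_perm: int = 500,
                       network_mask: bool = False, modality: str = "fpet") -> Path:
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, table, atlas = _load_cohort(data_dir, modality=modality)
    options = _default_options(seed, seed_region=seed_region, n_perm=n_perm,
                               frames=default_frame_window(images[0].n_frames))
    normalized = preprocess_cohort(images, atlas, options, normalize=True)
    result = connectivity_analysis(normalized, table, atlas, options,
                                   network_mask=network_mask)
    for sid, zmap in zip(table.subjects, result["zmaps"]):
        write_stat_map(zmap, out / f"{sid}_{modality}_z.nii.gz")
    write_stat_map(result["group_tmap"], out / f"group_t_{modality}.nii.gz")
    result["clusters"].table.to_csv(out / f"clusters_{modality}.tsv", sep="\t",
                                    index=False, float_format="%.8g")
    return out


def stage_dynamics(data_dir: str | Path, out_dir: str | Path, *, seed: int = 0,
                   regions: tuple[str, ...] = ("motor_cortex",),
                   n_perm: int = 5000) -> Path:
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, table, atlas = _load_cohort(data_dir)
    options = _default_options(seed, frames=default_frame_window(images[0].n_frames))
    normalized = preprocess_cohort(images, atlas, options, normalize=True)
    result = dynamics_analysis(normalized, table, atlas, options,
                               regions=regions, n_perm=n_perm)
    result["cov_table"].to_csv(out / "cov_table.tsv", sep="\t", index=False,
                               float_format="%.8g")
    result["group_stats"].to_csv(out / "cov_group_stats.tsv", sep="\t", index=False,
                                 float_format="%.8g")
    return out


def stage_clinical(data_dir: str | Path, out_dir: str | Path, *, seed: int = 0) -> Path:
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_subject_table(data_dir / "subjects.tsv")
    norms = _clinical.NormTable(pd.read_csv(data_dir / "norms.tsv", sep="\t"))
    report = clinical_analysis(table, norms)
    report.to_csv(out / "clinical_report.tsv", sep="\t", index=False,
                  float_format="%.8g")
    return out


def stage_classify(groupdiff_dir: str | Path, out_dir: str | Path, *, seed: int = 0) -> Path:
    groupdiff_dir, out = Path(groupdiff_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = pd.read_csv(groupdiff_dir / "cluster_features.tsv", sep="\t",
                        index_col="subject")
    kinds = json.load((groupdiff_dir / "cluster_feature_kind.json").open())
    labels = (feats.pop("group") == "PD").astype(int)
    matrix = _classify.FeatureMatrix(feats, labels, kinds)
    summary = classification_analysis(matrix)
    summary.to_csv(out / "auc_summary.tsv", sep="\t", index=False, float_format="%.8g")
    res_all = _classify.logistic_roc(matrix, "all")
    res_all.roc.to_csv(out / "roc_all.tsv", sep="\t", index=False, float_format="%.8g")
    d_rows = [
        {
            "feature": col,
            "cohens_d": _classify.cohens_d(
                feats.loc[labels == 0, col], feats.loc[labels == 1, col]
            ),
        }
        for col in feats.columns
    ]
    pd.DataFrame(d_rows).to_csv(out / "cohens_d.tsv", sep="\t", index=False,
                                float_format="%.8g")
    return out
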