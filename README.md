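# fpetdyn

Analysis of **constant-infusion functional FDG-PET ([18F]-FDG fPET) time
series**, built for group studies of neurodegenerative disease (the
motivating setting is Parkinson's disease vs healthy controls). Under a
slow continuous tracer infusion each subject yields a rising per-voxel
uptake curve — typically 90 one-minute frames — whose *level* carries
metabolic topography and whose *fluctuations around the trend* carry
functional information. `fpetdyn` implements the four analyses this
design enables, end-to-end, plus a synthetic-cohort generator with
emitted ground truth so everything is testable without patient data:

1. **Subject-by-time voxel-wise group comparison.** A mass-univariate
   flexible-factorial GLM over subject-frame observations (subject and
   frame indicator blocks, ANCOVA global-mean covariate), solved by
   pseudoinverse with explicit contrast estimability checks. Group
   inference is cluster-level family-wise-error control by permutation:
   subjects' ANCOVA-adjusted effect maps are compared with a voxel-wise
   two-sample t, and the null of the maximum suprathreshold cluster
   extent is built by relabelling groups (sign-flipping for one-sample
   maps). Clusters are retained at FWE p ≤ 0.05 with an extent > 20
   voxels.
2. **Seed-based metabolic connectivity.** Per subject, every voxel's
   global-ratio-normalised series is regressed on a seed region's mean
   series; the seed t-map is transformed to z via the t CDF
   (z = Φ⁻¹(F_t(t; df))). Subject z-maps enter one-sample or two-sample
   group maps. The engine is modality-agnostic, so BOLD-like series run
   through the same code and cross-modal correspondence is quantified by
   the dice coefficient of thresholded group maps.
3. **Glucose dynamics.** Region-wise coefficient of variation
   V_c(%) = σ/x̄·100 and temporal SNR μ_s/σ_s of the normalised series
   (sample SD throughout, so tSNR = 100/V_c exactly), permutation group
   tests with the rank effect size r = |Z|/√n, and correlation with
   clinical variables.
4. **Clinical and classification statistics.** Age-banded cognitive
   z-scores and the Level-II MCI rule (≥ 2 tests at or below −1.5 SD of
   age-matched norms), UPDRS-III hemibody motor lateralisation,
   Shapiro-Wilk-gated Welch/Mann-Whitney comparisons, Kruskal-Wallis with
   Holm-corrected pairwise rank tests, type-II ANCOVA with generalised
   eta-squared, and in-sample logistic ROC/AUC with Cohen's d on
   extracted cluster uptake.

## Worked example

`examples/` holds one narrative script per capability. The core loop:

```python
from fpetdyn.pipeline import AnalysisOptions, group_difference, preprocess_cohort
from fpetdyn.synthio import SimConfig, generate_cohort

config = SimConfig(seed=1)                       # 13 HC vs 14 PD, 90 x 60 s frames
images, table, atlas, truth = generate_cohort(config)
options = AnalysisOptions(seed=1, n_perm=200)    # last 30 frames, 5 mm smoothing
windowed = preprocess_cohort(images, atlas, options)
result = group_difference(windowed, table, atlas, options)
print(result["hypo"]["clusters"].table)
```

prints (seed 1) a cluster table for the HC > PD contrast:

```
 cluster_id  extent  peak_i  peak_j  peak_k  peak_stat    p_fwe  retained
          1     175       8       9       7   9.626852 0.004975      True
```

The 175-voxel retained cluster covers the planted bilateral
substantia-nigra hypometabolism (the generator reduces the nigral uptake
slope by 7% in the patient group); its FWE p sits at the resolution of
the 200-permutation null. The PD > HC contrast analogously recovers the
planted 122-voxel motor-cortex hypermetabolic cluster. Downstream,
`examples/04_glucose_dynamics.py` prints the elevated motor-cortex
coefficient of variation in patients (ΔV_c ≈ +0.37 percentage points,
permutation p ≈ 2·10⁻⁴, rank effect size r ≈ 0.78 at these conditions)
and its negative correlation with MoCA (r = −0.54, p = 0.0037), and
`examples/06_classification.py` the cluster-feature ROC/AUC.

A thin CLI mirrors the pipeline stages
(`fpetdyn simulate|preprocess|groupdiff|connectivity|dynamics|clinical|classify`),
each taking `--seed`, `--out-dir` and an optional `--config` YAML; all
file outputs are deterministic given the same inputs and seed.

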