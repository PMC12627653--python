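# Methods

## The measurement model

Constant tracer infusion yields, per voxel, a monotonically rising
activity curve whose slope reflects regional glucose consumption and
whose fluctuations around the trend reflect functional dynamics. All
analyses here work on co-registered 4D NIfTI series (one per subject)
with frame timing carried in a JSON sidecar; spatial normalisation and
reconstruction are assumed done upstream and are out of scope.

The synthetic cohort generator (`synthio`) emulates exactly the
statistical structure the analyses consume. Voxel *v* in region *r* of
subject *s* (group *g*) follows

    y_v(t) = scale_s · [ γ_{r,g,s} · b_r · t
                         + ν_{r,g,s} · ( Σ_k λ_{r,k} L_{k,s}(t)
                                         + w_priv · L_{r,s}(t) ) ] + ε ,

with *t* the mid-frame time in minutes, `L` latent signals (white noise
smoothed with a temporal Gaussian of FWHM 3 frames, then standardised —
simple, seedable, and spectrally slow like resting-state fluctuations),
and ε i.i.d. N(0, σ_ε²). Accumulation is linear rather than a
two-tissue compartment model: every downstream analysis uses
globally-normalised (relative) signal in which the shared kinetic shape
cancels, so linearity is the minimal model that preserves the analysed
structure; tracer kinetics (including dephosphorylation) are explicitly
not modelled.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| grid / voxel | 24×24×20 @ 4 mm | desk-scale analogue of a PET matrix |
| frames | 90 × 60 s | standard constant-infusion acquisition |
| cohort | 13 HC vs 14 PD | the motivating study size |
| baseline slope b_r | 1.0 /min | arbitrary activity units |
| γ (SN, PD) | 0.93 | ~7% nigral hypometabolism — a moderate regional change of the size FDG-PET group studies report |
| γ (motor cortex, PD) | 1.07 | matching hypermetabolism |
| SN asymmetry δ | 0.06 | left/right nigral split; the clinically more affected hemibody is contralateral to the more reduced SN |
| ν base / PD motor multiplier | 1.4 / 1.8× | planted glucose-dynamics effect; after the measurement-noise floor the *observable* CoV ratio is ≈1.5–1.7 |
| subject scatter | lognormal σ 0.15 on ν, σ 0.05 whole-image scale | inter-individual variability / injected-dose differences |
| w_priv | 0.35 | every region owns a private latent so its fluctuations are never degenerate, while shared-network coupling dominates (see below) |
| noise σ_ε | 1.0 | per-voxel, per-frame; ≈0.35 after 5 mm smoothing |
| networks | striato-nigro-thalamic (λ 1.0/0.9/0.8), default-mode (λ 1.0/0.9/0.9) | the planted connectivity truth: regions are "connected" iff they share a latent |
| clinical model | cognition z = −β(ν_motor−1)/0.4 + N(0, 0.8), β = 0.6 | plants the negative variability-cognition association; test scores = age-banded norm mean + norm SD·(cognition + N(0, 0.5)) |

The private-latent weight matters more than it looks: all voxels of a
region share one latent realisation, and a 30-frame window of an
FWHM-3-frame process has only ~10–15 effectively independent samples. At
w_priv much above ~0.4 an unlucky draw can sink a whole region's seed
correlation for one subject; 0.35 keeps the true seed-target correlation
high enough that voxel-level recovery holds per subject, which is a
property the test-suite asserts of the defaults.

What the generator does **not** emulate: Poisson/sinogram-level PET
noise, attenuation, motion, partial-volume effects, spatial
autocorrelation of noise beyond the applied smoothing, anatomically
realistic region shapes, or non-linear uptake kinetics. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed generative structure, not robustness to real-scanner artefacts.

## Preprocessing conventions

Frame windows are inclusive `[first, last]`, 0-based; the default window
is the last third of the series (60–89 for 90 frames), reflecting the low
early-frame activity of constant infusion. Smoothing is a per-frame
separable Gaussian (σ = FWHM/voxel/2√(2 ln 2) per axis) with reflect
boundaries; windowing and smoothing commute, and windowing is applied
first for speed. The global mean is the mean over the supplied
grey-matter mask — explicit and testable, rather than an intensity
heuristic. Ratio normalisation divides each frame by its in-mask mean
(output in-mask mean exactly 1); SUV scales by weight/dose and is
absorbed exactly by any subsequent ratio normalisation, which the suite
cross-checks. No reference-region ratio is applied beyond this.

## Group GLM and permutation inference

The flexible factorial design has one indicator column per subject, one
per frame, and optionally the mean-centred per-observation global mean
(ANCOVA normalisation). The design is deliberately over-parameterised;
estimation is by Moore-Penrose pseudoinverse and every contrast is
checked for estimability (c′ = c′X⁺X) before use. Error df = rows −
rank. Voxels fitted perfectly (residual variance at rounding level)
report t = 0 when the contrast estimate is also at rounding level, and a
guarded maximum (±10⁶) otherwise, so degenerate noise-free inputs never
produce 0/0 artefacts.

For group inference the factorial fit is collapsed to per-subject
effect maps (the subject coefficients, centred — any between-subject
contrast of them is uniquely defined despite the rank deficiency) and the
voxel-wise pooled two-sample t over subjects is the test statistic. This
makes the subject the exchangeable unit: relabelling groups permutes both
the numerator and the denominator of the statistic, which keeps the
max-cluster-extent permutation null well-behaved even when effects are
strong. (The alternative — permuting only the contrast against the fixed
within-subject error — is also exchangeable but becomes badly
conservative under strong effects: relabellings partially aligned with
the truth inherit large t values against an unchanged denominator.)

Cluster-forming threshold: the upper-p t-quantile at the map's df
(default p = 0.001 one-sided; configurable — the choice is a convention,
not derivable from first principles). Clusters are 26-connected
components. FWE p = (1 + #{permutation max extent ≥ observed}) /
(m + 1), ties counted with ≥ (conservative); when the number of distinct
relabellings (or sign patterns, for the one-sample map) is within the
requested budget the enumeration is exhaustive with the observed
labelling excluded. Retention requires p ≤ α **and** extent >
extent_min (default 20 voxels). The extent filter is a conservative
add-on; type-I-error calibration is therefore a property of the FWE
p-values alone, and the calibration simulations in the test-suite run at
cluster-forming p = 0.01, where the discrete extent distribution is rich
enough to resolve α = 0.05 (at very sparse thresholds the tie-conservative
p-values sit strictly below α — validity, not miscalibration).

Errors are treated as i.i.d. within subject in the voxel-wise fit; no
autocorrelation model is applied, matching common practice for these
designs, and the permutation inference does not rely on that assumption.

## Connectivity

The subject-level model is intercept + seed (a linear-drift nuisance is
available but off by default; ratio normalisation already removes the
shared trend). t→z uses the complementary tail of the t CDF and
saturates at |z| = 8.21, the double-precision-safe quantile bound —
reached only at numerically perfect fits such as the seed's own voxels.
z-maps are invariant to positive rescaling of the input series. Group
maps reuse the permutation engines (sign-flip one-sample by default,
extent filter off). For cross-modal comparison both modalities' group
maps are binarised at their retained-cluster voxels before the dice
coefficient; the binarisation rule is a package convention.

## Dynamics, clinical and classification conventions

Sample (n−1) SD everywhere, making tSNR = 100/CoV an exact identity
(asserted in tests). The permutation group test uses the absolute mean
difference, enumerating all C(n, n_a) relabellings when that count is ≤
20 000 (p = count/m, identity included) and Monte-Carlo with the
add-one correction otherwise. The rank effect size uses the
tie-corrected normal approximation of U without continuity correction.
Pearson is the default clinical correlation; Spearman by flag.

The MCI rule is inclusive at the boundary (z ≤ −1.5 is a deficit; ≥ 2
deficits required), composite cognition z is the unweighted mean of
available test z-scores, and norm tables are an explicit input (decade
age bands by default) so real normative data can be substituted. ANCOVA
uses type-II sums of squares without interactions; η²_G =
SS_effect/(SS_effect + SS_error) per term, with a condition-number guard
against collinear covariates.

Classification is in-sample by design (the descriptive small-cohort
procedure): maximum-likelihood logistic fit, ROC over fitted
probabilities, AUC through the rank identity with mid-rank ties. Complete
separation is detected (it is the expected outcome at the planted effect
sizes); a 10⁻⁶ ridge then stabilises the coefficients, which are flagged
non-identifiable, while the AUC is penalty-insensitive. Adding a
pure-noise feature can only raise in-sample AUC — documented optimism,
asserted as such in the tests, not celebrated. A leave-one-out option
exists for honest error rates but is off by default.

## Problem sizes used in validation

The simulation-based checks run at the package's default desk scale:
200 pure-noise phantoms (24×24×20, 30 frames, 27 subjects) with 500
permutations each for type-I calibration; 50 replicate cohorts for
cluster recovery and 100 for the CoV effect (200 and 2000 permutations
respectively); 3 cohorts × 27 subjects for per-subject connectivity
recovery. The acceptance script uses 500 permutations for map inference
and 10 000 for the CoV group test.

## Known limitations

Permutation FWE replaces random-field-theory corrections throughout —
assumption-light but Monte-Carlo-discrete at small permutation budgets.
Regions are spheres on a small grid; anatomical labelling, registration,
DICOM/BIDS handling, fMRI-style denoising, and across-subject covariance
"metabolic connectivity" are all out of scope. The clinical generative
model is a single linear pathway from motor-cortex fluctuation scale to
cognition; real cognitive batteries have domain structure the generator
does not attempt.
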