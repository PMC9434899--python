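# Methods

## Overview

`csfspace` measures three cerebrospinal-fluid compartments on an
AC/PC-aligned T1-like volume — the lateral ventricles, the high-convexity
subarachnoid space (HC-SAS), and the CSF spaces of the Sylvian fissure
region — normalizes each by intracranial volume (ICV), and forms the VOSS
index `V_LV / V_HC`. Because no patient imaging is distributed with the
package, every quantitative claim is validated on two kinds of synthetic
data with known truth: voxel phantoms (exact geometric ground truth) and
calibrated cohort samples (known population statistics).

## Phantom model

The head is a three-axis ellipsoid occupying 62.5% (left-right,
inferior-superior) and 75% (anterior-posterior) of the field of view,
with a WM core at 72% of the brain semi-axes and a GM shell outside it.
Defaults: 96^3 voxels at 2 mm isotropic, giving a ~1086 mL intracranial
volume. CSF compartments are parametric primitives:

- **Lateral ventricles** — two para-midline ellipsoids just above the AC-PC
  plane. `ventricle_scale` multiplies their volume; growth is in-plane
  (the vertical semi-axis is fixed) so enlarged ventricles never reach the
  high-convexity ROI, mirroring real anatomy where even severe
  ventriculomegaly does not extend to the vertex. Feasible up to
  `ventricle_scale ~ 6.6` at the default geometry; beyond that the generator
  raises rather than clipping silently.
- **High-convexity rind** — a shell of thickness `hc_sas_thickness` (mm) at
  the vertex, buried under a 4 mm GM "skin" so the Talairach bounding box
  (computed from the *eroded* brain mask) always contains it, restricted
  laterally and antero-posteriorly so it sits inside the high-convexity ROI
  box with margin.
- **Sylvian clefts** — horizontal CSF slabs of vertical width
  `sylvian_width` (mm) in the lateral half of each hemisphere, straddling
  the AC-PC plane, kept interior to the brain surface.

Intensity is the class mean (CSF 30, GM 80, WM 120 by default) times a
smooth multiplicative bias field (random quadratic with peak deviation
`bias_amplitude`) plus white Gaussian noise. The cohort noise setting used
throughout validation is `noise_sd = 4.0`, i.e. 5% of the GM mean. True
compartment volumes are exact voxel counts times voxel volume.

What the phantom deliberately does **not** model: cortical folding, skull
and extracranial tissue, cerebellum/brainstem, partial-volume mixing inside
a voxel (each voxel is pure tissue plus noise), Rician noise statistics, and
scanner artifacts beyond the smooth bias. Passing the recovery tests
therefore demonstrates correctness of the measurement chain on geometrically
idealized anatomy at realistic contrast and noise, not robustness to
real-scan segmentation difficulty.

Group presets (`control` / `INPH` / `AD`) set `ventricle_scale` 1.4/5.0/2.0,
`hc_sas_thickness` 5.0/2.5/5.0 mm and `sylvian_width` 6/10/8 mm —
ventriculomegaly with high-convexity tightness and Sylvian widening for
INPH, moderate ventriculomegaly for AD.

## Cohort calibration

Normalized volumes are modeled per group and region as log-normals —
volumes are positive and right-skewed, and the source statistics are
reported as median (IQR), which pins the log-normal exactly:
`sigma = ln(q3/q1) / (2 z_0.75)`, `mu = ln(median)`. VOSS ratios are
log-normals moment-matched to the printed mean ± SD
(`sigma^2 = ln(1 + (s/m)^2)`, `mu = ln m − sigma^2/2`).

Within-group correlation between regions is imposed with a Gaussian copula
on the log scale. The copula parameter is the closed-form inversion of the
bivariate log-normal Pearson correlation, so the *volume-scale* correlation
matches the target: `rho_log = ln(1 + r sqrt((e^{s1^2}−1)(e^{s2^2}−1))) /
(s1 s2)`. For small cohorts (8 ≤ n < 1000) one additional deterministic
de-biasing step runs: the sample Pearson correlation of strongly skewed
log-normal pairs is biased at small n (about −0.02 at n = 49 for the
ventricle/high-convexity pair), so the target is shifted by the measured
bias (2500 internal fixed-seed replicates at the requested n) before the
copula is built. Large cohorts use the analytic population calibration
unchanged. Controls get zero target correlation: no within-control
correlation is reported in the source material, so none is imposed (a
modeling default, not a claim).

An infeasible target (copula matrix not positive definite, or a Pearson
target outside the attainable range for the given skews) raises rather than
being projected.

## Preprocessing

- **Brain extraction**: 2-class Otsu threshold (background vs head),
  6-connected morphological closing, largest component, hole filling.
  Interior CSF excluded by the threshold returns as filled cavities, so the
  mask approximates the intracranial contents. A 4-class multi-Otsu was
  rejected: its lowest threshold lands inside the broad background-noise
  mode.
- **Bias correction**: fit a degree-3 (configurable 1-4) 3-D polynomial to
  log-intensity inside the mask by least squares and divide it out, with
  coordinates normalized to [−1, 1] per axis for conditioning. The fit is
  applied to *class-residual* log-intensity: each round classifies voxels
  (deterministic k-means), subtracts per-class log-means, and fits the
  polynomial to the remainder (2 rounds by default). Fitting the raw
  log-intensity instead lets the concentric tissue structure leak into the
  field estimate; the class-residual fit removes >95% of a quadratic bias
  field's RMS on phantoms and returns unbiased input unchanged. Output is
  rescaled to preserve the mean intensity inside the mask.
- **Tissue classification**: 1-D Lloyd k-means on intensity with
  deterministic percentile initialization (2nd/50th/98th; the extremes
  anchor the CSF and WM modes even when CSF is only a few percent of the
  brain). Class identity is assigned by mean ordering (CSF < GM < WM),
  never by cluster index; collapsed modes raise.
- **Partial volume**: linear two-class mixing between adjacent class means,
  `f = (I − m_low)/(m_high − m_low)` clamped to [0, 1], applied (by
  default) only at tissue interfaces — voxels with a 6-neighbor of a
  different hard class — and only outside a pure-tissue deadzone of 2 robust
  within-class SDs (`1.4826 × median |I − m_class|`). Both guards express
  that partial volume is interface mixing, not noise: without them,
  noise-induced fractional CSF on the many pure-GM voxels inside an ROI box
  inflates thin compartments by ~8%. Both vanish on noiseless data, where
  linear mixing applies in full and fraction volumes equal hard-label
  volumes exactly.
- **Registration**: 12-dof affine by Powell minimization of mean-squared
  error on a 4×/2× multi-resolution pyramid; deterministic, validated
  against identity at full resolution. Used for known-transform recovery;
  phantoms are generated already AC/PC-aligned in template-like space.

## Ventricle segmentation

Binary graph cut minimizing

    E(L) = sum_v D_v(L_v) + lambda sum_{(u,v) in N6} [L_u != L_v] w_uv

with `D_v(fg) = −ln(eps + p_v)`, `D_v(bg) = −ln(eps + 1 − p_v)`,
`p_v = c_v a_v / (c_v a_v + (1−c_v)(1−a_v))` the Bayes-normalized product of
the CSF fraction `c_v` and atlas prior `a_v`, and
`w_uv = exp(−(I_u−I_v)^2 / 2 sigma^2)`. Defaults: `lambda = 0.5`,
`eps = 1e-6`, 6-connectivity, `sigma` = median absolute neighbor intensity
difference (standard contrast-sensitive choices, all in config). The energy
is submodular, so max-flow/min-cut yields the global optimum; this is
verified against exhaustive enumeration on random ≤12-voxel instances.

Numerics: scipy's max-flow operates in int32, so capacities are scaled so
that an upper bound on the flow value (the cut value of the
all-background-but-seeds labeling) stays below 2^30 — quantization ≤1e-5 of
an energy unit on small problems. Terminal capacities are shifted per voxel
by `min(D_fg, D_bg)` to be non-negative (a labeling-independent constant).
The problem is cropped to the atlas-support bounding box plus a one-voxel
background ring, which provably leaves the minimizer unchanged. Hard seeds
(atlas core ≥ 0.9 eroded by 1, intersected with CSF fraction ≥ 0.5;
background outside the dilated atlas support) get capacities exceeding the
flow bound and are always respected.

The atlas prior for phantom work is the Gaussian-blurred (sigma = 2 voxels)
voxelwise mean of five training phantoms' true ventricle masks — the
package's stand-in for a manually drawn template ventricle propagated by
nonlinear registration, which is out of scope.

Post-processing retains the components overlapping a foreground seed;
morphological opening (ball radius `post_open_r`) is available but defaults
to 0: at 2 mm phantom resolution an r = 1 opening erodes ~2% of genuine
thin-ventricle boundary, and the seeded component filter already removes
false-positive tendrils (e.g. medial Sylvian CSF at the atlas-support
fringe). For 1 mm clinical data a nonzero radius is the natural setting.

## Talairach grid and ROIs

From the eroded-mask bounding box (erosion: 6-connectivity cross, radius 1)
and the AC/PC landmarks: 4 equal AP divisions anterior to AC, 3 between AC
and PC, 4 posterior to PC; 8 IS divisions above the AC-PC plane, 4 below;
4 sagittal divisions per hemisphere — 1056 cells. Boundary planes are kept
fractional; voxels join cells by voxel-center coordinate with half-open
intervals (last cell upper-inclusive), making the tessellation an exact
partition of the box. Named planes follow the grid-coordinate convention
(`vAC(+1)`, `vPC(−2)`, `AC-PC(+3)`, `M(±2)`).

ROI readings adopted (the end-cell inclusivity of the printed ranges is not
fully specified; the enumeration below reproduces the printed grid
arithmetic): high convexity = AC-PC(+3)..AC-PC(+8) × M(−1)..M(+1) ×
vAC(+1)..vPC(0) → 4 × 5 × 2 = 40 cells; Sylvian (per side) =
AC-PC(−2)..AC-PC(+3) × M(±2)..M(±4) × vAC(+2)..vPC(−1) → 6 × 5 × 2 = 60
cells. The two ROIs are disjoint by construction (sagittal ranges do not
meet). Left and right Sylvian volumes are summed into a single value.

## Volumetry

Regional CSF defaults to the sum of partial-volume CSF fractions over the
ROI times voxel volume (`volumetry_mode: fraction`); hard-label counting is
the config alternative — the source procedure does not say which was used,
so both are provided. The Sylvian measurement keeps only the largest
6-connected CSF component per hemisphere ROI before summing sides, removing
false positives. The lateral-ventricle volume comes from the graph-cut mask
(fraction-sum inside the mask in fraction mode), not from a grid box.
Normalized volumes are ratios of ICV (= brain-mask voxel count × voxel
volume); VOSS is identical computed from raw or normalized volumes.

## Statistics

Three-group comparisons use one-way ANOVA when every group passes
Shapiro-Wilk at alpha = 0.05, else Kruskal-Wallis (tie-corrected H,
chi-square p with k−1 df). The decision rule is a package choice the config
can override. Post-hoc: Dunn's rank test with Holm adjustment by default —
the standard rank-based follow-up — with Tukey HSD on rank-transformed data
as the configurable alternative mirroring a common clinical-paper phrasing;
pairwise p-values therefore depend on the chosen procedure and are not
treated as calibrated quantities. Pearson r carries the exact t-transform
p-value. ROC analysis fixes INPH as positive with higher VOSS positive,
computes the empirical curve over all observed thresholds, trapezoidal AUC
(ties get Mann-Whitney half credit), asserts the `AUC = U/(n1 n2)` identity
to 1e-12 on every call, and reports the Youden cutoff as the midpoint
between the maximizing observed score and the next lower score.

## Validation problem sizes

Phantom recovery runs 30 subjects at 96^3 × 2 mm with noise at 5% of the GM
mean; graph-cut optimality uses 200 random 12-voxel instances against
exhaustive search; cohort statistics use 500 ROC replicates at n = 49/59,
200 correlation replicates at the published group sizes, 10^4-subject
cohorts for quantile checks and 10^5 draws for moment checks. These sizes
give Monte-Carlo error comfortably below the tolerances tested (e.g. the
ROC oracle `Phi(dmu/sqrt(s1^2+s2^2)) ≈ 0.987` has replicate-mean SE below
0.001 at 500 replicates).

## Known limitations

- The phantom's pure-voxel construction means partial-volume *correction*
  is exercised mainly as a no-harm property (plus constructed-fixture
  tests), not against continuously mixed ground truth.
- The affine registration is validated on translations and isotropic
  scalings of phantoms; it is not a substitute for a full deformable
  registration pipeline on clinical data.
- AC/PC landmarks are taken as inputs (phantom truth or user-specified);
  automatic commissure detection is not implemented.
- Pairwise post-hoc p-values depend on the chosen procedure (Dunn vs Tukey
  on ranks); only the omnibus statistics are treated as calibrated.
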