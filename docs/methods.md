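# Methods

This note documents the models, conventions, parameter defaults and known
limitations of `lesionseg`. Everything stated here is computed by the code;
nothing is quoted from external results.

## Problem setting and assumptions

The pipeline segments a brain lesion from the rest of the brain using only
per-voxel intensity statistics — no atlas priors, no training data. Its core
assumption is distributional: within each tissue class (gray matter, white
matter, CSF, lesion) and each MRI modality, voxel intensities are
approximately Gaussian. That holds for magnitude MRI when the
signal-to-noise ratio is at least about 3; below that the noise becomes
Rician and the assumption degrades. The package therefore treats SNR ≥ 3 as
a validity condition: the phantom generator refuses class means closer than
3 sd to zero, and the mixture model is only claimed to be appropriate in
that regime.

Inputs must already be co-registered to a common grid (nominally 1 mm
isotropic). Registration, skull stripping and bias-field correction are
preconditions, not operations of this package; `volumes_io.read_subject`
enforces grid agreement and rejects mismatched shapes or voxel sizes.

## Pipeline

1. **Cohort normalization.** For each modality independently, every
   subject's volume is rescaled so its within-brain-mask mean equals the
   cohort grand mean (the mean of subject means). This is a pure rescale:
   within-subject contrast is untouched, the map is idempotent, and a
   subject with zero mean is a hard error. Masked statistics are essential —
   background zeros would otherwise dominate. Any common-mean target
   necessarily depends on every subject's brightness, so rescaling one input
   subject changes the output only through the cohort-wide target mean; the
   test suite asserts equivariance in exactly that form.
2. **Feature extraction** (25 columns, fixed order; see README table).
   Deterministic — no randomness anywhere in this stage.
3. **Standardization.** Columns are z-scored with the population sd;
   a column with zero range maps to all-zeros.
4. **Clustering** into k = 4 groups by K-means and GMM-EM.
5. **Evaluation** lesion-versus-rest against the truth mask.

## Feature conventions

* **Smoothing**: isotropic Gaussian, σ = 3 mm converted to voxels via the
  voxel size; image border handled by edge replication so a constant volume
  smooths to itself exactly. For head images the border is background, so
  the border rule is immaterial in practice.
* **Window statistics**: cubic window of half-width 5 mm (±5 voxels at
  1 mm → 11³ = 1331 positions), center voxel excluded, so a deep-interior
  voxel has 1330 neighbors. Only in-mask, in-grid neighbors enter the
  statistic — no padding values are fabricated; a voxel with no surviving
  neighbor is a hard error. Four statistics are used per modality
  ({mean, variance, p10, p90}; 4 × 4 = 16 columns). The per-voxel median is
  available as a drop-in replacement for any of the four
  (`window_stat_names`), but only four fit the 25-column layout.
  For non-unit voxel sizes the half-width in voxels is
  `round(5 mm / voxel_size)`.
* **Percentiles** interpolate linearly between order statistics (the numpy
  `percentile` convention), and variance is the population variance
  (ddof = 0). All statistics are computed over the *sorted* finite neighbor
  values; the vectorized implementation is bit-identical to a naive
  per-voxel loop, which the tests assert literally (`==`, no tolerance).
* **Distance feature**: Euclidean mm distance to the geometric center of
  the full grid (`(n−1)/2` per axis), not the mask centroid.

## K-means conventions

The algorithm statement (assign to nearest center, recompute means, repeat
until stable) leaves several choices open; all are deterministic here:

* initialization samples k **distinct** rows of the data, uniformly over
  distinct rows, without replacement under the seed — this makes
  initialization invariant to row order and duplication;
* squared Euclidean distances are computed from explicit differences (not
  the expanded inner-product identity) so exact ties stay exact; ties break
  to the lowest cluster index;
* an emptied cluster is re-seeded at the row farthest from its stale center
  and the event is logged;
* convergence = unchanged assignments (equivalent to unchanged centers in
  exact arithmetic, robust in floating point), with a 300-iteration cap;
* 10 independent restarts by default, best final distortion wins. The
  distortion trace is checked non-increasing every iteration (slack
  1e-9 relative, covering round-off only).

## GMM-EM numerics

* Densities and responsibilities are evaluated in log space (Cholesky
  factorization, log-sum-exp with per-row max subtraction).
* Every covariance gets `+1e-6·I` (in standardized-feature units) before
  factorization. Full covariances are the default, matching the model's
  Σₖ; 25-dimensional voxel data makes the regularization necessary at
  tissue boundaries where features are nearly collinear.
* Initialization defaults to one K-means fit (per-cluster means,
  covariances, proportional weights); the pipeline reuses the K-means
  solution it already computed, so the two methods share one clustering
  seed. A `random` mode (random rows + global covariance) exists for
  independence studies.
* Convergence: absolute log-likelihood change below `1e-6·N`, capped at
  500 iterations (flagged if hit). The trace is checked non-decreasing with
  slack `1e-8 + 1e-12·|ℓ|` — the absolute floor is the guarantee the tests
  assert; the relative term covers round-off accumulation on cohort-sized
  problems where |ℓ| ~ 10⁶.
* A component whose effective count collapses below 1e-8 is re-spread at
  the observation with the lowest maximum responsibility, with the global
  covariance and renormalized weights (logged; never observed on the
  default phantoms, but required for robustness on real voxel data).
* Hard labels are the argmax responsibility, ties to the lowest index.

## Evaluation conventions

* Metrics use the standard binary definitions over **brain-mask voxels
  only** (background would inflate specificity arbitrarily):
  accuracy = (tp+tn)/total, misclassification = 1 − accuracy,
  sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), fpr = fp/(fp+tn).
  Undefined rates (empty positive or negative class) are reported as
  missing with a warning, never as 0.
* Clusters are anonymous, and the mapping to "lesion" is explicit:
  the cluster maximizing Dice overlap with the truth mask (ties to the
  lowest index). This evaluation-time oracle matching is the least
  bias-prone convention; a deployment-mode heuristic (lesion = cluster
  with highest mean FLAIR) is provided separately.
* Method comparison: paired two-sided t-test per metric across subjects
  (Wilcoxon signed-rank optional); identical per-subject values are
  degenerate and reported as p = 1 with a warning. Size-performance
  association: Pearson correlation (Spearman optional) of lesion voxel
  count with each metric, per method.

## The phantom generator

The generator emulates the *structure* of a sub-acute stroke segmentation
dataset — four co-registered modalities plus an expert-style lesion mask on
a 1 mm grid — under the exact distributional assumption the clustering
makes: per-class, per-modality Gaussian intensities.

* **Geometry**: nested ellipsoids (semi-axes `brain_radius · (1, 0.85,
  0.8)`); WM core out to normalized radius 0.8, GM band to 0.95, CSF shell
  to 1.0, giving roughly 46/34/14 % WM/GM/CSF shares plus the lesion. One
  spherical lesion per subject overwrites the tissue it covers; the spec
  validator rejects spheres that escape the brain.
* **Default grid** 64³ at 1 mm: large enough that interior windows reach
  full 1330-neighbor support, small enough that a 10-subject cohort runs in
  a few minutes on one CPU.
* **Default contrasts** (arbitrary units, sd 5 everywhere): CSF bright on
  T2 and suppressed on FLAIR, WM brightest on T1, lesion hyperintense on
  FLAIR and DWI — the qualitative contrast pattern of the four sequences.
  Every class pair is separated by ≥ 4 pooled sds in at least one modality,
  and every mean/sd ratio is ≥ 3 (both are validated invariants).
* **Default lesion radii** 10.5–11.0 mm across the 10-subject cohort,
  about twice the 5 mm window half-width (see limitations for why this
  ratio is the designed-for regime). `size_sweep_spec` builds cohorts
  sweeping 5–11 mm for size-dependence studies.
* **Reproducibility**: per-subject streams are spawned from a single seed
  sequence; the same spec + seed is bit-identical, and all pipeline seeds
  derive from one integer.

What the phantom does **not** model: real anatomy, partial-volume mixing at
tissue interfaces, bias fields, Rician noise at low SNR, multi-focal or
irregular lesions, registration error. Consequently, passing the end-to-end
tests demonstrates that the algorithms and their plumbing are correct under
the model's own assumptions — not that real-data accuracy will be
comparable. On real images the Gaussian-class assumption is only
approximate and class overlap is much larger.

## Windowed features at the lesion boundary (known limitation)

The ±5 mm neighborhood statistics of a voxel near the lesion surface mix
lesion and healthy intensities. This creates a "rim" population — healthy
voxels within ~4 mm outside the surface whose 20 contextual columns (16
window + 4 smoothed) are pulled toward the lesion — forming a continuum
between the WM and lesion clusters in feature space.

Whether the distortion-optimal k = 4 clustering attaches that rim to the
lesion cluster is a mass-balance question, and it is bistable in the lesion
radius:

* **small lesions** (radius ≲ 2× the window half-width): the rim outweighs
  the pure-lesion core, the lesion cluster's center is dragged into the
  continuum, and the *global* optimum absorbs several thousand rim voxels
  as false positives (specificity ~0.92 at radius 7–10 mm on this
  geometry). This is not a local-minimum artifact — oracle-initialized
  K-means converges to the same solution — and EM inherits it.
* **very large lesions** (radius ≳ 11.6 mm here): the lesion's own
  contaminated inner shell plus the within-lesion gradient of the
  distance-to-center feature carry enough variance that the optimum splits
  the lesion itself, costing sensitivity instead.

Between the two regimes — lesion radius near twice the window half-width —
the pure-lesion solution is the global optimum and both methods segment
essentially perfectly. The default cohort is placed in that regime, which
is also where real sub-acute stroke lesions sit relative to a 5 mm window
on full-resolution brains. The `analysis/06_size_sweep.py` study and
`size_sweep_spec` deliberately cross into the small-lesion regime: there,
specificity falls with shrinking lesions and the boundary effect becomes
the dominant error source, mirroring the boundary misclassification that
plagues this family of methods on real data.

## Problem sizes

Defaults were chosen so the full study runs comfortably on one CPU: the
default cohort is 10 subjects × ~44 500 in-mask voxels × 25 features
(≈ 4 minutes end-to-end for both methods), parameter-recovery checks use
n = 5000 two-dimensional mixtures, and exhaustive K-means oracles
enumerate all partitions only for n ≤ 10.
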