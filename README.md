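# lesionseg

Unsupervised brain-lesion segmentation from multi-modal MRI, built as a
tested, reusable pipeline: per-voxel feature extraction from four registered
modalities (T1-weighted, T2-weighted, FLAIR, DWI), clustering of the voxels
into four tissue groups — gray matter, white matter, CSF, and lesion — by
K-means and by Gaussian-mixture expectation-maximization (both implemented
here from first principles), and confusion-matrix evaluation against
ground-truth lesion masks. A synthetic phantom module generates cohorts with
known truth, so the whole pipeline is exercised end-to-end without any
external download.

## Who this is for

Researchers who want an auditable, minimal reference implementation of the
classic clustering approach to stroke-lesion segmentation: no training data,
no learned models — just intensity statistics, two textbook algorithms
written out in full, and honest evaluation machinery.

## The model

Each in-mask voxel is summarized by a 25-dimensional feature vector:

| columns | content |
|---------|---------|
| 1–4     | raw intensities (T1, T2, FLAIR, DWI) |
| 5–8     | Gaussian-smoothed intensities, σ = 3 mm |
| 9–24    | {mean, variance, 10th, 90th percentile} of the ±5 mm cubic neighborhood (11³ voxels at 1 mm; center excluded → 1330 neighbors), per modality |
| 25      | Euclidean distance to the grid center (mm) |

Columns are z-scored, then clustered with k = 4:

* **K-means** minimizes the distortion
  `D = Σᵢ Σ_{x∈Cᵢ} ‖x − Cᵢ‖²` by Lloyd iteration (random-sample
  initialization, best of 10 restarts, assignment-stability convergence).
* **GMM-EM** fits `p(x) = Σₖ πₖ N(x | μₖ, Σₖ)` with full covariances by
  expectation-maximization in log space, seeded from the K-means solution;
  the log-likelihood trace is guaranteed non-decreasing.

Clusters are anonymous; at evaluation time the cluster with maximal Dice
overlap against the truth mask is designated "lesion" and scored
lesion-versus-rest with accuracy, misclassification rate, sensitivity,
specificity and false-positive rate over brain-mask voxels.

The phantom generates nested-ellipsoid anatomy (CSF shell, GM band, WM core)
plus one spherical lesion; every voxel's intensity is drawn from its tissue
class's Gaussian with mean/sd ≥ 3 in all modalities — the signal-to-noise
regime in which MRI noise is approximately Gaussian, which is exactly the
assumption the mixture model encodes.

## Worked example

```python
from lesionseg import default_spec, run_cohort

df = run_cohort(seed=0)          # simulate -> normalize -> features ->
                                 # k-means + GMM-EM -> confusion metrics
print(df[["subject_id", "method", "accuracy", "sensitivity",
          "specificity", "lesion_voxels"]].head(4).to_string(index=False))
```

prints

```
subject_id method  accuracy  sensitivity  specificity  lesion_voxels
phantom000 kmeans  0.999955     0.999791     0.999975           4776
phantom000    gmm  0.999325     0.993719     1.000000           4776
phantom001 kmeans  1.000000     1.000000     1.000000           4896
phantom001    gmm  0.999348     0.994077     1.000000           4896
```

Each row scores one subject's lesion-versus-rest segmentation within the
brain mask: `phantom000` has a 4776-voxel truth lesion; K-means recovers
99.98 % of its voxels (sensitivity) while labeling 0.0025 % of non-lesion
voxels as lesion (1 − specificity). On this default cohort — well-separated
tissue classes, lesion radii 10.5–11 mm — both methods exceed 0.99 accuracy
on every subject, and a paired t-test finds the sub-0.1 % differences
between them (`lesionseg.compare_methods`).

The same pipeline runs from the shell, one stage at a time:

```bash
lesionseg simulate  --out scratch/cohort --seed 0 --n-subjects 10
lesionseg normalize --manifest scratch/cohort/manifest.txt --out scratch/norm
lesionseg features  --subject scratch/norm/phantom000 --out scratch/f000.tsv
lesionseg segment   --method gmm --features scratch/f000.tsv \
                    --subject scratch/norm/phantom000 --out scratch/l000.nii.gz
lesionseg evaluate  --pred scratch/l000.nii.gz \
                    --truth scratch/cohort/phantom000/lesion_mask.nii.gz \
                    --mask  scratch/cohort/phantom000/mask.nii.gz \
                    --out scratch/m000.csv
```

The numbered scripts under `analysis/` run the full study in order:
cohort simulation (01), normalization + feature extraction (02),
segmentation by both methods (03), evaluation (04), the paired method
comparison (05), and a lesion-size sweep (06) that probes how performance
depends on lesion volume. Tables land in `results/`, volumes in `scratch/`.

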