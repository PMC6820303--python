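#!/usr/bin/env python
"""Score both methods' label volumes against the ground-truth lesion masks.

Reads scratch/labels/ and scratch/cohort/, writes the per-subject confusion
metrics to results/segmentation_metrics.csv and prints the cohort summary.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from lesionseg.evaluate import cohort_report, evaluate_segmentation, lesion_volume, summarize
from lesionseg.volumes_io import read_label_volume, read_subject_dir

BASE = os.path.join(os.path.dirname(__file__), "..", "scratch")
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    with open(os.path.join(BASE, "cohort", "manifest.txt")) as fh:
        dirs = [line.strip() for line in fh if line.strip()]
    metrics, volumes = [], {}
    for d in dirs:
        sid = os.path.basename(d)
        v = read_subject_dir(d)
        truth = read_label_volume(os.path.join(d, "lesion_mask.nii.gz")) > 0
        volumes[sid], _ = lesion_volume(truth, v.voxel_size_mm)
        for method in ("kmeans", "gmm"):
            labels = read_label_volume(
                os.path.join(BASE, "labels", f"{sid}_{method}.nii.gz"))
            metrics.append(evaluate_segmentation(
                labels, truth, v.brain_mask, subject_id=sid, method=method))
    df = cohort_report(metrics, volumes)
    os.makedirs(RESULTS, exist_ok=True)
    df.to_csv(os.path.join(RESULTS, "segmentation_metrics.csv"), index=False)
    print(df[["subject_id", "method", "accuracy", "sensitivity",
              "specificity", "lesion_voxels"]].to_string(index=False))
    print("\ncohort summary (mean / sd per method):")
    print(summarize(df).round(4).to_string())


if __name__ == "__main__":
    main()
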