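#!/usr/bin/env python
"""Cohort intensity normalization and 25-feature extraction.

Reads scratch/cohort/, writes normalized volumes to scratch/norm/ and
standardized per-subject feature tables to scratch/features/.
"""

import os
import sys
import time

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from lesionseg.features import build_feature_matrix, save_feature_matrix, standardize_features
from lesionseg.volumes_io import normalize_cohort, read_subject_dir, write_subject

BASE = os.path.join(os.path.dirname(__file__), "..", "scratch")


def main() -> None:
    with open(os.path.join(BASE, "cohort", "manifest.txt")) as fh:
        dirs = [line.strip() for line in fh if line.strip()]
    subjects = [read_subject_dir(d) for d in dirs]
    normed = normalize_cohort(subjects)
    norm_dir = os.path.join(BASE, "norm")
    feat_dir = os.path.join(BASE, "features")
    os.makedirs(feat_dir, exist_ok=True)
    manifest = []
    for v in normed:
        d = os.path.join(norm_dir, v.subject_id)
        write_subject(v, d)
        manifest.append(d)
        t0 = time.time()
        f = standardize_features(build_feature_matrix(v))
        save_feature_matrix(f, os.path.join(feat_dir, f"{v.subject_id}.tsv"))
        print(f"{v.subject_id}: {f.n_voxels} voxels x {len(f.column_names)} "
              f"features ({time.time() - t0:.1f}s)")
    with open(os.path.join(norm_dir, "manifest.txt"), "w") as fh:
        fh.write("\n".join(manifest) + "\n")


if __name__ == "__main__":
    main()
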