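#!/usr/bin/env python
"""Cluster every subject's feature table with K-means and GMM-EM.

Reads scratch/features/, writes per-method label volumes to scratch/labels/.
The GMM is initialized from each subject's K-means solution, so the two
methods share one K-means fit per subject.
"""

import os
import sys
import time

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from lesionseg.features import load_feature_matrix
from lesionseg.gmm_em import gmm_fit
from lesionseg.kmeans import kmeans_fit
from lesionseg.pipeline import subject_seed
from lesionseg.volumes_io import read_subject_dir, write_label_volume

BASE = os.path.join(os.path.dirname(__file__), "..", "scratch")
SEED = 0


def main() -> None:
    feat_dir = os.path.join(BASE, "features")
    out_dir = os.path.join(BASE, "labels")
    os.makedirs(out_dir, exist_ok=True)
    names = sorted(f for f in os.listdir(feat_dir) if f.endswith(".tsv"))
    for i, name in enumerate(names):
        sid = name[: -len(".tsv")]
        f = load_feature_matrix(os.path.join(feat_dir, name))
        v = read_subject_dir(os.path.join(BASE, "norm", sid))
        seed = subject_seed(SEED, i)

        t0 = time.time()
        km = kmeans_fit(f.values, k=4, seed=seed, n_restarts=10)
        model, _, gm_labels = gmm_fit(f.values, K=4, seed=seed,
                                      kmeans_labels=km.assignments)
        print(f"{sid}: k-means distortion {km.distortion:.0f} "
              f"({km.n_iter} it), EM loglik {model.loglik_trace[-1]:.0f} "
              f"({len(model.loglik_trace) - 1} it, converged={model.converged}) "
              f"[{time.time() - t0:.1f}s]")

        for method, labels in (("kmeans", km.assignments), ("gmm", gm_labels)):
            vol = np.zeros(v.shape, dtype=np.int16)
            ii, jj, kk = f.voxel_index.T
            vol[ii, jj, kk] = labels + 1
            write_label_volume(vol, v.voxel_size_mm,
                               os.path.join(out_dir, f"{sid}_{method}.nii.gz"))


if __name__ == "__main__":
    main()
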