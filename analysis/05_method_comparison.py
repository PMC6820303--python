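#!/usr/bin/env python
"""Paired comparison of K-means vs GMM-EM across the cohort.

Reads results/segmentation_metrics.csv; writes the per-metric paired
two-sided p-values to results/method_comparison.csv.  A large p-value means
no detectable performance difference between the two clustering methods.
"""

import os
import sys
import warnings

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from lesionseg.evaluate import compare_methods

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    df = pd.read_csv(os.path.join(RESULTS, "segmentation_metrics.csv"))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pvals = compare_methods(df)
    for w in caught:
        print(f"note: {w.message}")
    out = pd.DataFrame([pvals])
    out.to_csv(os.path.join(RESULTS, "method_comparison.csv"), index=False)
    for metric, p in pvals.items():
        verdict = "no significant difference" if p > 0.05 else "significant difference"
        print(f"{metric}: p = {p:.4f} ({verdict} at alpha = 0.05)")


if __name__ == "__main__":
    main()
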