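"""Per-voxel 25-dimensional feature vectors from a normalized multi-modal subject.

Column order (fixed, documented):

==========  =================================================================
columns     content
==========  =================================================================
1-4         raw intensities: T1, T2, FLAIR, DWI
5-8         Gaussian-smoothed intensities (sigma 3 mm): T1, T2, FLAIR, DWI
9-24        cubic-window neighborhood statistics over +-5 mm (11^3 voxels at
            1 mm), center voxel excluded (1330 neighbors at full interior
            support): {mean, variance, p10, p90} x {T1, T2, FLAIR, DWI},
            statistic-major
25          Euclidean distance (mm) of the voxel to the geometric grid center
==========  =================================================================

Rows are the in-mask voxels, in C (row-major) grid order.

Window statistics use only in-mask, in-grid neighbors — no padding values are
fabricated at boundaries.  Every statistic is computed over the *sorted*
finite neighbor values; percentiles use linear interpolation between order
statistics (the numpy ``percentile`` convention), variance is the population
variance (``ddof=0``).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter

from .volumes_io import MODALITIES, MultiModalVolume

DEFAULT_SIGMA_MM = 3.0
DEFAULT_HALF_WIDTH_MM = 5.0
#: window statistics used for feature columns 9-24 (any may be swapped for
#: "median", e.g. ``window_stats=("mean", "variance", "median", "p90")``).
DEFAULT_WINDOW_STATS = ("mean", "variance", "p10", "p90")
_STAT_PERCENTILE = {"median": 50.0, "p10": 10.0, "p90": 90.0}


@dataclass
class FeatureMatrix:
    """N_voxels x 25 feature values with the voxel coordinates of each row."""

    values: np.ndarray
    voxel_index: np.ndarray  # (N, 3) integer grid coordinates
    column_names: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.column_names)} columns"
            )
        if self.voxel_index.shape != (self.values.shape[0], 3):
            raise ValueError("voxel_index must be (N, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]


def smooth_modalities(
    v: MultiModalVolume, sigma_mm: float = DEFAULT_SIGMA_MM
) -> dict[str, np.ndarray]:
    """Convolve each modality with an isotropic Gaussian of physical width sigma_mm.

    Sigma in voxels is ``sigma_mm / voxel_size`` per axis.  The image border
    is edge-replicated (``mode="nearest"``), so a constant volume smooths to
    itself exactly; for registered head images the border is zero background
    far from the brain, making the border rule immaterial in practice.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    sigma_vox = [sigma_mm / s for s in v.voxel_size_mm]
    return {
        m: gaussian_filter(v.modality(m), sigma=sigma_vox, mode="nearest")
        for m in MODALITIES
    }


def distance_to_center(v: MultiModalVolume) -> np.ndarray:
    """Euclidean distance in mm from each voxel center to the geometric grid center.

    The center is the midpoint of the full grid, ``(n_i - 1) / 2`` in voxel
    coordinates per axis — not the mask centroid.
    """
    shape = v.shape
    axes = [
        ((np.arange(n, dtype=float) - (n - 1) / 2.0) * s) ** 2
        for n, s in zip(shape, v.voxel_size_mm)
    ]
    return np.sqrt(
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )


def _percentile_from_sorted(sorted_rows: np.ndarray, n: int, q: float) -> np.ndarray:
    """Percentile q of the first ``n`` entries of each pre-sorted row.

    Replicates numpy's linear-interpolation convention bit-for-bit: virtual
    index ``(q/100) * (n-1)``, then ``a + t*(b-a)`` for t < 0.5 and
    ``b - (b-a)*(1-t)`` otherwise.
    """
    virtual = (q / 100.0) * (n - 1)
    lo = int(np.floor(virtual))
    hi = int(np.ceil(virtual))
    t = virtual - lo
    a = sorted_rows[:, lo]
    b = sorted_rows[:, hi]
    diff = b - a
    if t >= 0.5:
        return b - diff * (1 - t)
    return a + diff * t


def window_stats(
    volume: np.ndarray,
    mask: np.ndarray,
    half_width_mm: float = DEFAULT_HALF_WIDTH_MM,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    stats: tuple[str, ...] = DEFAULT_WINDOW_STATS,
    chunk_rows: int = 8192,
) -> dict[str, np.ndarray]:
    """Neighborhood statistics over a centered cubic window, per in-mask voxel.

    The window spans ``+-round(half_width_mm / voxel_size)`` voxels per axis
    (11^3 = 1331 positions at 1 mm); the center voxel itself is excluded, so
    a deep-interior voxel has 1330 neighbors.  Neighbors outside the mask or
    the grid are dropped from the statistic.

    Returns one flat array per requested statistic, aligned with the in-mask
    voxels in C order.

    Raises
    ------
    ValueError
        If any in-mask voxel has no surviving neighbor (cannot happen for a
        connected mask of two or more voxels).
    """
    if mask.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    unknown = set(stats) - ({"mean", "variance"} | set(_STAT_PERCENTILE))
    if unknown:
        raise ValueError(f"unknown window statistics: {sorted(unknown)}")

    w = [max(1, round(half_width_mm / s)) for s in voxel_size_mm]
    pad = [(wi, wi) for wi in w]
    vol_p = np.pad(volume.astype(np.float64), pad, constant_values=np.nan)
    mask_p = np.pad(mask, pad, constant_values=False)
    vol_p[~mask_p] = np.nan

    win_shape = tuple(2 * wi + 1 for wi in w)
    windows = sliding_window_view(vol_p, win_shape)  # view, no copy
    center_flat = int(np.ravel_multi_index(w, win_shape))

    ii, jj, kk = np.nonzero(mask)
    n_rows = ii.size
    out = {s: np.empty(n_rows, dtype=np.float64) for s in stats}

    for start in range(0, n_rows, chunk_rows):
        sl = slice(start, min(start + chunk_rows, n_rows))
        block = windows[ii[sl], jj[sl], kk[sl]].reshape(sl.stop - sl.start, -1).copy()
        block[:, center_flat] = np.nan  # center voxel excluded
        block.sort(axis=1)  # NaNs sort to the end
        counts = np.count_nonzero(~np.isnan(block), axis=1)
        if np.any(counts == 0):
            bad = np.nonzero(counts == 0)[0][0] + start
            coord = (ii[bad], jj[bad], kk[bad])
            raise ValueError(f"voxel {coord} has no in-mask neighbors in its window")
        # Group rows by neighbor count so each statistic runs over a dense
        # (rows, n) prefix — identical arithmetic to a per-row computation.
        for n in np.unique(counts):
            rows = np.nonzero(counts == n)[0]
            prefix = block[rows, :n]
            for s in stats:
                if s == "mean":
                    vals = prefix.mean(axis=1)
                elif s == "variance":
                    vals = prefix.var(axis=1)
                else:
                    vals = _percentile_from_sorted(prefix, int(n), _STAT_PERCENTILE[s])
                out[s][rows + start] = vals
    return out


def neighbor_counts(
    mask: np.ndarray,
    half_width_mm: float = DEFAULT_HALF_WIDTH_MM,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Number of surviving window neighbors per in-mask voxel (center excluded)."""
    w = [max(1, round(half_width_mm / s)) for s in voxel_size_mm]
    pad = [(wi, wi) for wi in w]
    mask_p = np.pad(mask, pad, constant_values=False)
    win_shape = tuple(2 * wi + 1 for wi in w)
    windows = sliding_window_view(mask_p, win_shape)
    ii, jj, kk = np.nonzero(mask)
    counts = windows[ii, jj, kk].reshape(ii.size, -1).sum(axis=1)
    return counts - 1  # center voxel is itself in-mask


def feature_column_names(stats: tuple[str, ...] = DEFAULT_WINDOW_STATS) -> tuple[str, ...]:
    names = [f"{m}_raw" for m in MODALITIES]
    names += [f"{m}_smooth" for m in MODALITIES]
    for s in stats:
        names += [f"{m}_win_{s}" for m in MODALITIES]
    names.append("dist_center")
    return tuple(names)


def build_feature_matrix(
    v: MultiModalVolume,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    half_width_mm: float = DEFAULT_HALF_WIDTH_MM,
    window_stat_names: tuple[str, ...] = DEFAULT_WINDOW_STATS,
) -> FeatureMatrix:
    """Assemble the 25-column feature matrix for the in-mask voxels of one subject."""
    if len(window_stat_names) != 4:
        raise ValueError("exactly four window statistics are required (columns 9-24)")
    mask = v.brain_mask
    smoothed = smooth_modalities(v, sigma_mm=sigma_mm)
    dist = distance_to_center(v)

    cols = [v.modality(m)[mask] for m in MODALITIES]
    cols += [smoothed[m][mask] for m in MODALITIES]
    per_modality = {
        m: window_stats(
            v.modality(m), mask, half_width_mm=half_width_mm,
            voxel_size_mm=v.voxel_size_mm, stats=window_stat_names,
        )
        for m in MODALITIES
    }
    for s in window_stat_names:
        cols += [per_modality[m][s] for m in MODALITIES]
    cols.append(dist[mask])

    values = np.column_stack(cols)
    voxel_index = np.column_stack(np.nonzero(mask)).astype(np.int64)
    return FeatureMatrix(
        values=values,
        voxel_index=voxel_index,
        column_names=feature_column_names(window_stat_names),
        subject_id=v.subject_id,
    )


def standardize_features(f: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column (population sd); constant columns map to all-zeros.

    Idempotent: standardizing an already-standardized matrix returns it
    unchanged up to floating point.
    """
    if f.n_voxels < 2:
        raise ValueError("standardization needs at least two rows")
    mu = f.values.mean(axis=0)
    sd = f.values.std(axis=0)
    # exact-range test: a truly constant column maps to zeros even when the
    # column mean carries round-off
    constant = np.ptp(f.values, axis=0) == 0
    centered = f.values - mu
    z = np.where(constant, 0.0, centered / np.where(constant | (sd == 0), 1.0, sd))
    return FeatureMatrix(
        values=z, voxel_index=f.voxel_index, column_names=f.column_names,
        subject_id=f.subject_id,
    )


def save_feature_matrix(f: FeatureMatrix, path: str | os.PathLike) -> None:
    """Persist as a TSV table plus a JSON sidecar (``<path>.json``)."""
    df = pd.DataFrame(f.values, columns=list(f.column_names))
    for ax, name in enumerate(("i", "j", "k")):
        df.insert(ax, f"voxel_{name}", f.voxel_index[:, ax])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "subject_id": f.subject_id,
        "n_voxels": int(f.n_voxels),
        "columns": list(f.column_names),
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_feature_matrix(path: str | os.PathLike) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    cols = tuple(meta["columns"])
    return FeatureMatrix(
        values=df[list(cols)].to_numpy(dtype=np.float64),
        voxel_index=df[["voxel_i", "voxel_j", "voxel_k"]].to_numpy(dtype=np.int64),
        column_names=cols,
        subject_id=meta["subject_id"],
    )
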