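"""Feature extraction: smoothing, window statistics, distance, assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lesionseg.features import (
    build_feature_matrix,
    distance_to_center,
    feature_column_names,
    load_feature_matrix,
    neighbor_counts,
    save_feature_matrix,
    smooth_modalities,
    standardize_features,
    window_stats,
)
from lesionseg.volumes_io import MODALITIES, MultiModalVolume


def make_volume(arrays=None, value=3.0, shape=(16, 16, 16), mask=None):
    if arrays is None:
        arrays = {m: np.full(shape, value) for m in MODALITIES}
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return MultiModalVolume(brain_mask=mask, subject_id="toy", **arrays)


# ---------------------------------------------------------------- smoothing

def test_smoothing_preserves_constant():
    v = make_volume(value=4.2)
    out = smooth_modalities(v)
    interior = np.s_[6:10, 6:10, 6:10]
    for m in MODALITIES:
        np.testing.assert_allclose(out[m][interior], 4.2, rtol=1e-10)


def test_point_source_mass_conserved():
    arr = np.zeros((41, 41, 41))
    arr[20, 20, 20] = 7.0
    v = make_volume({m: arr for m in MODALITIES}, shape=arr.shape,
                    mask=np.ones(arr.shape, bool))
    out = smooth_modalities(v, sigma_mm=3.0)
    assert out["t1"].sum() == pytest.approx(7.0, rel=1e-6)


def test_impulse_matches_gaussian_formula():
    # value at offset k voxels, relative to the peak, is exp(-k^2 / (2 sigma^2))
    arr = np.zeros((41, 41, 41))
    arr[20, 20, 20] = 1.0
    v = make_volume({m: arr for m in MODALITIES}, shape=arr.shape,
                    mask=np.ones(arr.shape, bool))
    sm = smooth_modalities(v, sigma_mm=3.0)["t1"]
    for k in (1, 2, 5):
        ratio = sm[20 + k, 20, 20] / sm[20, 20, 20]
        assert ratio == pytest.approx(np.exp(-(k**2) / 18.0), rel=1e-10)


# ---------------------------------------------------------- window statistics

def test_constant_volume_window_stats():
    c = 2.5
    mask = np.ones((12, 12, 12), bool)
    out = window_stats(np.full((12, 12, 12), c), mask)
    np.testing.assert_array_equal(out["mean"], c)
    np.testing.assert_array_equal(out["p10"], c)
    np.testing.assert_array_equal(out["p90"], c)
    np.testing.assert_array_equal(out["variance"], 0.0)


def test_deep_interior_neighbor_count_is_1330():
    mask = np.ones((13, 13, 13), bool)
    counts = neighbor_counts(mask)
    center = counts.reshape(13, 13, 13)[6, 6, 6]
    assert center == 1330


def test_5cube_enumeration_oracle():
    # center voxel of an all-mask 5^3 volume, half width 1: stats over its
    # 26 neighbors must match direct enumeration
    vol = np.arange(1.0, 126.0).reshape(5, 5, 5)
    mask = np.ones((5, 5, 5), bool)
    out = window_stats(vol, mask, half_width_mm=1.0)
    idx = np.ravel_multi_index((2, 2, 2), (5, 5, 5))
    vals = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                vals.append(vol[2 + di, 2 + dj, 2 + dk])
    vals = np.sort(np.array(vals))
    assert len(vals) == 26
    assert out["mean"][idx] == np.mean(vals)
    assert out["variance"][idx] == np.var(vals)
    assert out["p10"][idx] == np.percentile(vals, 10)
    assert out["p90"][idx] == np.percentile(vals, 90)


def test_window_stats_match_naive_loop_exactly():
    rng = np.random.default_rng(42)
    vol = rng.normal(50, 10, (16, 16, 16))
    i, j, k = np.indices((16, 16, 16))
    mask = ((i - 7.5) ** 2 / 49 + (j - 7.5) ** 2 / 36 + (k - 7.5) ** 2 / 42) <= 1.0
    out = window_stats(vol, mask, half_width_mm=5.0,
                       stats=("mean", "variance", "median", "p10", "p90"))

    ii, jj, kk = np.nonzero(mask)
    for r in range(ii.size):
        vals = []
        for di in range(-5, 6):
            for dj in range(-5, 6):
                for dk in range(-5, 6):
                    if di == dj == dk == 0:
                        continue
                    x, y, z = ii[r] + di, jj[r] + dj, kk[r] + dk
                    if 0 <= x < 16 and 0 <= y < 16 and 0 <= z < 16 and mask[x, y, z]:
                        vals.append(vol[x, y, z])
        v = np.sort(np.array(vals))
        assert out["mean"][r] == np.mean(v)
        assert out["variance"][r] == np.var(v)
        assert out["median"][r] == np.percentile(v, 50)
        assert out["p10"][r] == np.percentile(v, 10)
        assert out["p90"][r] == np.percentile(v, 90)


def test_p10_never_exceeds_p90(small_subject):
    v = small_subject.volumes
    out = window_stats(v.flair, v.brain_mask, voxel_size_mm=v.voxel_size_mm,
                       stats=("p10", "p90"))
    assert np.all(out["p10"] <= out["p90"])


def test_isolated_voxel_without_neighbors_rejected():
    mask = np.zeros((9, 9, 9), bool)
    mask[4, 4, 4] = True
    with pytest.raises(ValueError, match="no in-mask neighbors"):
        window_stats(np.ones((9, 9, 9)), mask, half_width_mm=1.0)


# ------------------------------------------------------------------ distance

def test_distance_zero_at_center_of_odd_grid():
    v = make_volume(shape=(9, 9, 9),
                    arrays={m: np.zeros((9, 9, 9)) for m in MODALITIES},
                    mask=np.ones((9, 9, 9), bool))
    d = distance_to_center(v)
    assert d[4, 4, 4] == 0.0


def test_corner_distance_64_grid():
    shape = (64, 64, 64)
    v = make_volume(shape=shape, arrays={m: np.zeros(shape) for m in MODALITIES},
                    mask=np.ones(shape, bool))
    d = distance_to_center(v)
    assert d[0, 0, 0] == pytest.approx(np.sqrt(3) * 31.5, rel=1e-12)


def test_distance_reflection_symmetric():
    shape = (10, 12, 8)
    v = make_volume(shape=shape, arrays={m: np.zeros(shape) for m in MODALITIES},
                    mask=np.ones(shape, bool))
    d = distance_to_center(v)
    for ax in range(3):
        np.testing.assert_allclose(d, np.flip(d, axis=ax), rtol=1e-12)


# ------------------------------------------------------------------ assembly

def test_feature_matrix_shape_and_projection(small_subject):
    v = small_subject.volumes
    f = build_feature_matrix(v)
    assert f.values.shape == (int(v.brain_mask.sum()), 25)
    assert len(f.column_names) == 25
    # columns 1-4 are the raw intensities at each voxel, exactly
    i, j, k = f.voxel_index.T
    for c, m in enumerate(MODALITIES):
        np.testing.assert_array_equal(f.values[:, c], v.modality(m)[i, j, k])


def test_constant_subject_features():
    shape = (14, 14, 14)
    vals = {"t1": 1.0, "t2": 2.0, "flair": 3.0, "dwi": 4.0}
    v = make_volume({m: np.full(shape, c) for m, c in vals.items()}, shape=shape,
                    mask=np.ones(shape, bool))
    f = build_feature_matrix(v)
    # interior rows: raw/smoothed/window-mean columns all equal the constant
    counts = neighbor_counts(v.brain_mask)
    interior = counts == 1330
    for c, m in enumerate(MODALITIES):
        np.testing.assert_allclose(f.values[interior, c], vals[m], rtol=1e-12)
        np.testing.assert_allclose(f.values[interior, 4 + c], vals[m], rtol=1e-10)
        np.testing.assert_allclose(f.column(f"{m}_win_mean")[interior], vals[m], rtol=1e-12)
        np.testing.assert_allclose(f.column(f"{m}_win_variance")[interior], 0.0, atol=1e-18)
    # last column is the distance field
    d = distance_to_center(v)
    i, j, k = f.voxel_index.T
    np.testing.assert_array_equal(f.values[:, 24], d[i, j, k])


def test_median_can_replace_a_window_statistic(small_subject):
    f = build_feature_matrix(small_subject.volumes,
                             window_stat_names=("mean", "variance", "median", "p90"))
    assert "flair_win_median" in f.column_names
    assert len(f.column_names) == 25


# -------------------------------------------------------------- standardize

def test_standardize_definition_and_idempotence(small_subject):
    f = build_feature_matrix(small_subject.volumes)
    z = standardize_features(f)
    assert np.abs(z.values.mean(axis=0)).max() <= 1e-12
    var = z.values.var(axis=0)
    assert np.all((np.abs(var - 1) < 1e-9) | (var == 0))
    z2 = standardize_features(z)
    np.testing.assert_allclose(z2.values, z.values, atol=1e-12)


def test_standardize_two_row_hand_case():
    from lesionseg.features import FeatureMatrix

    values = np.array([[0.0], [2.0]])
    f = FeatureMatrix(values=values, voxel_index=np.zeros((2, 3), dtype=np.int64),
                      column_names=("x",))
    z = standardize_features(f)
    np.testing.assert_allclose(z.values[:, 0], [-1.0, 1.0], atol=1e-15)


@given(st.floats(min_value=-100, max_value=100, allow_nan=False))
def test_standardize_maps_constant_columns_to_zero(c):
    from lesionseg.features import FeatureMatrix

    values = np.column_stack([np.full(5, c), np.arange(5.0)])
    f = FeatureMatrix(values=values, voxel_index=np.zeros((5, 3), dtype=np.int64),
                      column_names=("a", "b"))
    z = standardize_features(f)
    np.testing.assert_array_equal(z.values[:, 0], 0.0)


def test_feature_matrix_round_trip(tmp_path, small_subject):
    f = build_feature_matrix(small_subject.volumes)
    p = tmp_path / "features.tsv"
    save_feature_matrix(f, p)
    back = load_feature_matrix(p)
    np.testing.assert_allclose(back.values, f.values, rtol=1e-15)
    np.testing.assert_array_equal(back.voxel_index, f.voxel_index)
    assert back.column_names == f.column_names
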