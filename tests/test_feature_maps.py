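"""Filters, gray-level matrices, windowed feature maps and the stack."""

import numpy as np
import pytest

from voxbag.feature_maps import (
    DIRECTIONS_13,
    FILTER_NAMES,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    FeatureConfig,
    apply_filter,
    compute_feature_stack,
    glcm_features,
    glcm_window,
    glrlm_features,
    glrlm_window,
    make_offsets,
)
from voxbag.feature_maps import _log_kernel
from voxbag.image_core import QuantizedImage, VolumetricImage, quantize
from voxbag import _texture

from conftest import make_image, make_mask


class TestOffsets:
    def test_counts(self):
        assert len(make_offsets({1})) == 13
        assert len(make_offsets({1, 2})) == 26
        assert make_offsets({1, 2}).offsets.shape == (26, 3)

    def test_no_duplicate_or_sign_opposite_directions(self):
        offs = [tuple(v) for v in make_offsets({1}).offsets]
        for i, a in enumerate(offs):
            for b in offs[i + 1:]:
                assert a != b
                assert tuple(-x for x in a) != b

    def test_empty_error(self):
        with pytest.raises(ValueError):
            make_offsets(set())
        with pytest.raises(ValueError):
            make_offsets({0})


class TestFilters:
    def test_log_kernel_zero_sum(self):
        k = _log_kernel(2.0, 4.0)
        assert abs(k.sum()) < 1e-6 * np.abs(k).sum()

    def test_constant_image_zero_log_response(self):
        img = make_image(np.full((12, 12, 12), 5.0))
        out = apply_filter(img, "log")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_impulse_response_is_abs_kernel(self):
        n = 13
        arr = np.zeros((n, n, n))
        arr[6, 6, 6] = 1.0
        out = apply_filter(make_image(arr), "log")
        k = _log_kernel(2.0, 4.0)
        expected = np.zeros((n, n, n))
        expected[2:11, 2:11, 2:11] = np.abs(k[::-1, ::-1, ::-1])
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_sobel_ramp_matches_kernel_oracle(self):
        # ramp along axis 0: response = |ramp slope| * (sum of the 3D Sobel
        # kernel weights), built here from the separable [1,2,1]/[-1,0,1] parts
        n = 9
        slope = 0.75
        arr = slope * np.indices((n, n, n))[0].astype(float)
        out = apply_filter(make_image(arr), "sobel")
        deriv = np.array([-1.0, 0.0, 1.0])
        smooth = np.array([1.0, 2.0, 1.0])
        k3d = np.einsum("i,j,k->ijk", deriv, smooth, smooth)
        expected = 0.0
        for di in range(3):
            for dj in range(3):
                for dk in range(3):
                    expected += k3d[di, dj, dk] * (-(di - 1)) * slope
        assert out.values[4, 4, 4] == pytest.approx(abs(expected), rel=1e-6)

    def test_maps_non_negative(self, rng):
        img = make_image(rng.normal(size=(10, 10, 10)))
        for name in FILTER_NAMES:
            fm = apply_filter(img, name)
            assert fm.values.min() >= 0.0

    def test_anisotropic_rejected(self, rng):
        img = VolumetricImage(rng.random((5, 5, 5)), spacing=(1.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="isotropic"):
            apply_filter(img, "log")

    def test_unknown_filter(self, rng):
        with pytest.raises(ValueError):
            apply_filter(make_image(rng.random((5, 5, 5))), "laws")


def naive_glcm_counts(q, center, offsets, window):
    """Independent per-pair enumeration oracle."""
    half = window // 2
    shape = q.values.shape
    lo = [max(0, c - half) for c in center]
    hi = [min(s, c + half + 1) for c, s in zip(center, shape)]
    C = np.zeros((q.num_levels, q.num_levels))
    for off in offsets:
        for a0 in range(lo[0], hi[0]):
            for a1 in range(lo[1], hi[1]):
                for a2 in range(lo[2], hi[2]):
                    b = (a0 + off[0], a1 + off[1], a2 + off[2])
                    if not all(lo[i] <= b[i] < hi[i] for i in range(3)):
                        continue
                    la, lb = q.values[a0, a1, a2], q.values[b]
                    if la == 0 or lb == 0:
                        continue
                    C[la - 1, lb - 1] += 1
                    C[lb - 1, la - 1] += 1
    return C


def naive_glrlm_counts(q, center, directions, window):
    """Independent maximal-run enumeration oracle."""
    half = window // 2
    shape = q.values.shape
    lo = [max(0, c - half) for c in center]
    hi = [min(s, c + half + 1) for c, s in zip(center, shape)]
    R = np.zeros((q.num_levels, window))

    def inside(p):
        return all(lo[i] <= p[i] < hi[i] for i in range(3))

    for d in directions:
        for s0 in range(lo[0], hi[0]):
            for s1 in range(lo[1], hi[1]):
                for s2 in range(lo[2], hi[2]):
                    lv = q.values[s0, s1, s2]
                    if lv == 0:
                        continue
                    prev = (s0 - d[0], s1 - d[1], s2 - d[2])
                    if inside(prev) and q.values[prev] == lv:
                        continue
                    ln, cur = 1, (s0 + d[0], s1 + d[1], s2 + d[2])
                    while inside(cur) and q.values[cur] == lv:
                        ln += 1
                        cur = tuple(cur[i] + d[i] for i in range(3))
                    R[lv - 1, min(ln, window) - 1] += 1
    return R


class TestGlcmWindow:
    def test_constant_window_single_cell(self):
        q = QuantizedImage(np.full((5, 5, 5), 3, dtype=np.int16), 4, (0, 1))
        C = glcm_window(q, (2, 2, 2), make_offsets({1}))
        assert C[2, 2] == pytest.approx(1.0)
        assert C.sum() == pytest.approx(1.0)

    def test_stripe_vs_enumeration_oracle(self):
        # 2-level stripes along axis 0, single axis offset
        vals = (1 + (np.indices((5, 5, 5))[0] % 2)).astype(np.int16)
        q = QuantizedImage(vals, 2, (0, 1))
        offsets = make_offsets({1})
        C = glcm_window(q, (2, 2, 2), offsets)
        expected = naive_glcm_counts(q, (2, 2, 2), offsets.offsets, 5)
        np.testing.assert_allclose(C, expected / expected.sum())

    def test_symmetric(self, small_quantized):
        offsets = make_offsets({1, 2})
        for center in [(0, 0, 0), (3, 4, 5), (7, 7, 7)]:
            C = glcm_window(small_quantized, center, offsets)
            np.testing.assert_array_equal(C, C.T)

    def test_center_outside_error(self, small_quantized):
        with pytest.raises(ValueError):
            glcm_window(small_quantized, (9, 0, 0), make_offsets({1}))


class TestGlcmFeatures:
    def test_degenerate_single_cell(self):
        C = np.zeros((4, 4))
        C[1, 1] = 1.0
        f = glcm_features(C)
        assert f["glcm_energy"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_inertia"] == 0.0
        assert f["glcm_inverse_difference_moment"] == 1.0

    def test_uniform_matrix_closed_form(self):
        C = np.full((4, 4), 1 / 16)
        f = glcm_features(C)
        assert f["glcm_energy"] == pytest.approx(1 / 16)
        assert f["glcm_entropy"] == pytest.approx(4.0)  # log2(16) bits

    def test_formula_by_formula_oracle(self):
        C = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(C)
        # independent hand computation: levels 1 and 2, equal diagonal mass
        mu, var = 1.5, 0.25
        assert f["glcm_energy"] == pytest.approx(0.5)
        assert f["glcm_inverse_difference_moment"] == pytest.approx(1.0)
        assert f["glcm_entropy"] == pytest.approx(1.0)
        assert f["glcm_inertia"] == pytest.approx(0.0)
        sxy = 1 * 1 * 0.5 + 2 * 2 * 0.5
        assert f["glcm_haralick_correlation"] == pytest.approx((sxy - mu**2) / var)
        assert f["glcm_correlation"] == pytest.approx(1.0)
        shade = ((1 + 1 - 2 * mu) ** 3) * 0.5 + ((2 + 2 - 2 * mu) ** 3) * 0.5
        prom = ((1 + 1 - 2 * mu) ** 4) * 0.5 + ((2 + 2 - 2 * mu) ** 4) * 0.5
        assert f["glcm_cluster_shade"] == pytest.approx(shade)
        assert f["glcm_cluster_prominence"] == pytest.approx(prom)

    def test_relabel_invariance_of_symmetric_features(self, rng):
        # Energy, Entropy, Inertia, IDM are invariant under levels -> L+1-levels
        for _ in range(5):
            C = rng.random((5, 5))
            C = C + C.T
            C /= C.sum()
            f = glcm_features(C)
            g = glcm_features(C[::-1, ::-1])
            for name in (
                "glcm_energy",
                "glcm_entropy",
                "glcm_inertia",
                "glcm_inverse_difference_moment",
            ):
                assert f[name] == pytest.approx(g[name], abs=1e-12)


class TestGlrlmWindow:
    def test_constant_window_axis_runs(self):
        q = QuantizedImage(np.full((5, 5, 5), 2, dtype=np.int16), 3, (0, 1))
        axes = np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1)])
        R = glrlm_window(q, (2, 2, 2), directions=axes)
        # each axis direction: 25 lines, one full-length run each
        assert R[1, 4] == 75
        assert R.sum() == 75

    def test_alternating_pattern_runs_length_one(self):
        vals = (1 + (np.indices((5, 5, 5))[0] % 2)).astype(np.int16)
        q = QuantizedImage(vals, 2, (0, 1))
        R = glrlm_window(q, (2, 2, 2), directions=np.array([(1, 0, 0)]))
        assert R[:, 1:].sum() == 0
        assert R.sum() == 125

    def test_random_window_vs_enumeration_oracle(self, rng):
        vals = rng.integers(1, 4, size=(3, 3, 3)).astype(np.int16)
        q = QuantizedImage(vals, 3, (0, 1))
        R = glrlm_window(q, (1, 1, 1), window=3)
        expected = naive_glrlm_counts(q, (1, 1, 1), DIRECTIONS_13, 3)
        np.testing.assert_array_equal(R, expected)


class TestGlrlmFeatures:
    def test_unit_length_runs(self):
        R = np.zeros((4, 5))
        R[0, 0] = 3
        R[2, 0] = 5
        f = glrlm_features(R)
        assert f["glrlm_short_run_emphasis"] == 1.0
        assert f["glrlm_long_run_emphasis"] == 1.0

    def test_single_run_closed_form(self):
        R = np.zeros((6, 5))
        lam, L = 3, 4  # one run of length 4 at level 3
        R[lam - 1, L - 1] = 1
        f = glrlm_features(R)
        assert f["glrlm_long_run_emphasis"] == L**2
        assert f["glrlm_short_run_emphasis"] == 1 / L**2
        assert f["glrlm_high_grey_level_run_emphasis"] == lam**2
        assert f["glrlm_low_grey_level_run_emphasis"] == 1 / lam**2
        assert f["glrlm_grey_level_nonuniformity"] == 1.0
        assert f["glrlm_run_length_nonuniformity"] == 1.0
        assert f["glrlm_long_run_high_grey_level_emphasis"] == L**2 * lam**2

    def test_random_matrix_vs_direct_formula_oracle(self, rng):
        R = rng.integers(0, 5, size=(4, 5)).astype(float)
        R[0, 0] += 1  # ensure non-empty
        f = glrlm_features(R)
        nr = R.sum()
        sre = sum(
            R[i, l] / (l + 1) ** 2 for i in range(4) for l in range(5)
        ) / nr
        gln = sum(R[i, :].sum() ** 2 for i in range(4)) / nr
        srhgle = sum(
            R[i, l] * (i + 1) ** 2 / (l + 1) ** 2
            for i in range(4)
            for l in range(5)
        ) / nr
        assert f["glrlm_short_run_emphasis"] == pytest.approx(sre)
        assert f["glrlm_grey_level_nonuniformity"] == pytest.approx(gln)
        assert f["glrlm_short_run_high_grey_level_emphasis"] == pytest.approx(srhgle)

    def test_empty_matrix_degenerate(self):
        f = glrlm_features(np.zeros((3, 5)))
        assert all(v == 0.0 for v in f.values())


class TestCompiledPathVsNaive:
    """The production (numba) windowed maps must equal a naive per-voxel
    recomputation through the reference single-window operations."""

    def test_oracle_equivalence_small_volume(self, rng):
        shape = (9, 9, 9)
        levels = rng.integers(1, 6, size=shape).astype(np.int16)
        roi = rng.random(shape) < 0.7
        levels[~roi] = 0
        q = QuantizedImage(levels, 5, (0, 1))
        offsets = make_offsets({1, 2})
        idx = np.argwhere(levels > 0)[:40]
        feats, ndeg = _texture.texture_feature_maps(
            levels.astype(np.int64),
            np.ascontiguousarray(idx),
            np.ascontiguousarray(offsets.offsets),
            np.ascontiguousarray(offsets.directions),
            5,
            5,
        )
        for row, center in zip(feats, idx):
            C = naive_glcm_counts(q, tuple(center), offsets.offsets, 5)
            total = C.sum()
            expected_g = glcm_features(C / total if total else C)
            R = naive_glrlm_counts(q, tuple(center), offsets.directions, 5)
            expected_r = glrlm_features(R)
            got = dict(zip(GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES, row))
            for name, val in {**expected_g, **expected_r}.items():
                assert got[name] == pytest.approx(val, abs=1e-10), name


class TestFeatureStack:
    def test_two_modalities_42_columns(self, tiny_features):
        stack = tiny_features.stack
        assert stack.n_features == 42
        assert len(stack.feature_names) == 42
        assert sum(n.startswith("CT:") for n in stack.feature_names) == 21
        assert sum(n.startswith("PET:") for n in stack.feature_names) == 21
        assert np.all(np.isfinite(stack.matrix))

    def test_one_modality_21_columns(self, rng):
        img = make_image(rng.normal(size=(10, 10, 10)))
        roi = make_mask(np.zeros((10, 10, 10)))
        roi.values[3:7, 3:7, 3:7] = True
        stack = compute_feature_stack([img], roi, FeatureConfig(num_levels=8))
        assert stack.n_features == 21
        assert stack.n_voxels == roi.voxel_count

    def test_row_count_and_raster_order(self, rng):
        img = make_image(rng.normal(size=(8, 8, 8)))
        roi = make_mask(rng.random((8, 8, 8)) < 0.3)
        roi.values[4, 4, 4] = True
        stack = compute_feature_stack([img], roi, FeatureConfig(num_levels=4))
        np.testing.assert_array_equal(stack.voxel_index, np.argwhere(roi.values))

    def test_translation_invariance(self, rng):
        # keep the ROI + filter support well away from the volume border so
        # boundary padding does not differ between the two placements
        arr = rng.normal(size=(20, 20, 20))
        roi1 = np.zeros((20, 20, 20), dtype=bool)
        roi1[8:12, 8:12, 8:12] = True
        arr2 = np.roll(arr, 2, axis=0)
        roi2 = np.roll(roi1, 2, axis=0)
        cfg = FeatureConfig(num_levels=6)
        s1 = compute_feature_stack([make_image(arr)], make_mask(roi1), cfg)
        s2 = compute_feature_stack([make_image(arr2)], make_mask(roi2), cfg)
        np.testing.assert_allclose(s1.matrix, s2.matrix, atol=1e-9)

    def test_mismatched_grid_error(self, rng):
        img = make_image(rng.random((6, 6, 6)))
        roi = make_mask(np.ones((5, 5, 5)))
        with pytest.raises(ValueError):
            compute_feature_stack([img], roi)

    def test_subsample_deterministic(self, rng):
        img = make_image(rng.normal(size=(10, 10, 10)))
        roi = make_mask(np.ones((10, 10, 10)))
        cfg = FeatureConfig(num_levels=4, max_voxels=50, subsample_seed=3)
        s1 = compute_feature_stack([img], roi, cfg)
        s2 = compute_feature_stack([img], roi, cfg)
        assert s1.n_voxels == 50
        np.testing.assert_array_equal(s1.voxel_index, s2.voxel_index)
        np.testing.assert_array_equal(s1.matrix, s2.matrix)
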