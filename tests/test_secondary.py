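"""FRAP normalisation, co-localisation, transects, integrated intensity and
the Mann-Whitney comparison."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condensate_quant import (
    FlatTraceError,
    SceneParams,
    ZeroVarianceError,
    compare_groups,
    generate_frap_series,
    generate_two_channel_scene,
    integrated_intensity,
    normalize_frap,
    pearson_colocalization,
    transect_profile,
)
from conftest import make_image


class TestNormalizeFrap:
    def test_affine_map_example(self):
        raw = [10, 10, 10, 10, 10, 2, 4, 6, 8]
        t = normalize_frap(raw, n_prebleach=5)
        np.testing.assert_allclose(t.normalised, [1, 1, 1, 1, 1, 0, 0.25, 0.5, 0.75])
        assert t.normalised.min() == 0.0 and t.normalised.max() == 1.0

    def test_shallow_bleach_flagged_excluded(self):
        raw = [10.0] * 5 + [7.0, 7.5, 8.0]  # only a 30 % drop
        t = normalize_frap(raw)
        assert t.excluded
        assert t.bleach_fraction == pytest.approx(0.3)

    def test_deep_bleach_not_excluded(self):
        raw = [10.0] * 5 + [2.0, 4.0, 6.0]
        assert not normalize_frap(raw).excluded

    def test_synthetic_trace_plateau_matches_mobile_fraction(self):
        trace = generate_frap_series(
            mobile_fraction=0.6, recovery_rate=0.15, noise_sd=0.3, rng_seed=8
        )
        t = normalize_frap(trace)
        assert not t.excluded
        assert t.normalised[-10:].mean() == pytest.approx(0.6, abs=0.05)

    def test_idempotent(self):
        raw = generate_frap_series(rng_seed=3)
        once = normalize_frap(raw)
        twice = normalize_frap(once.normalised)
        np.testing.assert_allclose(twice.normalised, once.normalised, atol=1e-12)

    def test_flat_trace_raises(self):
        with pytest.raises(FlatTraceError):
            normalize_frap([5.0] * 10)


class TestColocalization:
    def test_affine_identical_channels_r_is_one(self, default_scene):
        img, _ = default_scene
        ch2 = make_image(2.0 * img.data + 5.0, voxel_size=img.voxel_size)
        res = pearson_colocalization(img, ch2)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_partial_scene_recovers_target_rho(self):
        ch1, ch2, _ = generate_two_channel_scene(SceneParams(rng_seed=13), "partial", rho=0.8)
        res = pearson_colocalization(ch1, ch2, mask="whole-image")
        assert res.pearson_r == pytest.approx(0.8, abs=0.05)

    def test_independent_noise_channels_null_r(self):
        rng = np.random.default_rng(5)
        a = make_image(rng.uniform(1, 10, (16, 96, 96)))
        b = make_image(rng.uniform(1, 10, (16, 96, 96)))
        res = pearson_colocalization(a, b, mask="whole-image")
        assert res.n_voxels >= 1e5
        assert abs(res.pearson_r) < 0.1

    def test_zero_variance_raises(self):
        a = make_image(np.ones((4, 8, 8)))
        b = make_image(np.random.default_rng(0).uniform(0, 1, (4, 8, 8)))
        with pytest.raises(ZeroVarianceError):
            pearson_colocalization(a, b, mask="whole-image")

    def test_mismatched_grids_rejected(self):
        a = make_image(np.ones((4, 8, 8)))
        b = make_image(np.zeros((4, 8, 9)))
        with pytest.raises(ValueError, match="differ"):
            pearson_colocalization(a, b)

    def test_otsu_union_mask_smaller_than_whole_image(self, default_scene):
        img, _ = default_scene
        res = pearson_colocalization(img, img, mask=None)
        assert res.mask_used == "otsu-union"
        assert 10 <= res.n_voxels < img.data.size

    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        offset=st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_r_invariant_under_per_channel_affine_rescale(self, scale, offset):
        rng = np.random.default_rng(17)
        base = rng.uniform(0, 50, (6, 16, 16))
        other = base + rng.normal(0, 10, base.shape)
        a = make_image(base)
        b1 = make_image(np.clip(other, 0, None))
        b2 = make_image(scale * np.clip(other, 0, None) + offset)
        r1 = pearson_colocalization(a, b1, mask="whole-image").pearson_r
        r2 = pearson_colocalization(a, b2, mask="whole-image").pearson_r
        assert r2 == pytest.approx(r1, abs=1e-9)


class TestTransect:
    def test_constant_image_constant_profile(self):
        a = make_image(np.full((3, 10, 10), 4.0))
        prof = transect_profile(a, a, (5, 0), (5, 9), z=1)
        np.testing.assert_allclose(prof["ch1"], 4.0)
        assert len(prof["ch1"]) == 10

    def test_series_length_is_chebyshev_steps(self):
        a = make_image(np.zeros((3, 20, 20)))
        prof = transect_profile(a, a, (0, 0), (10, 4), z=0)
        assert len(prof["ch1"]) == 11

    def test_colocalized_condensate_peaks_at_same_index(self, clean_scene):
        img, gt = clean_scene
        z, y, x = np.argwhere(gt.condensate_mask)[0]
        prof = transect_profile(img, img, (int(y), 0), (int(y), img.shape[2] - 1), z=int(z))
        assert int(np.argmax(prof["ch1"])) == int(np.argmax(prof["ch2"]))
        assert prof["ch1"].max() == pytest.approx(gt.true_c_den)

    def test_zero_length_line_rejected(self):
        a = make_image(np.zeros((3, 8, 8)))
        with pytest.raises(ValueError, match="zero-length"):
            transect_profile(a, a, (2, 2), (2, 2), z=0)

    def test_endpoint_outside_grid_rejected(self):
        a = make_image(np.zeros((3, 8, 8)))
        with pytest.raises(ValueError, match="outside"):
            transect_profile(a, a, (0, 0), (7, 9), z=0)


class TestIntegratedIntensity:
    def test_uniform_image_yields_zero(self):
        img = make_image(np.full((5, 20, 20), 3.0))
        lvl = integrated_intensity(img)
        assert lvl.integrated_intensity_per_slice == 0.0

    def test_doubling_brightness_doubles_level(self):
        base = SceneParams(rng_seed=31)
        bright = base.model_copy(
            update=dict(c_tot=2 * base.c_tot, background_level=2 * base.background_level)
        )
        from condensate_quant import generate_scene

        img1, _ = generate_scene(base)
        img2, _ = generate_scene(bright)
        l1 = integrated_intensity(img1, background_roi=(0, 0))
        l2 = integrated_intensity(img2, background_roi=(0, 0))
        assert l2.integrated_intensity_per_slice / l1.integrated_intensity_per_slice == pytest.approx(
            2.0, rel=0.05
        )

    def test_duplicated_slices_leave_per_slice_value_unchanged(self, clean_scene):
        img, _ = clean_scene
        doubled = make_image(np.concatenate([img.data, img.data]), voxel_size=img.voxel_size)
        l1 = integrated_intensity(img, background_roi=(0, 0))
        l2 = integrated_intensity(doubled, background_roi=(0, 0))
        assert l2.integrated_intensity_per_slice == pytest.approx(
            l1.integrated_intensity_per_slice, rel=1e-9
        )
        assert l2.n_slices == 2 * l1.n_slices

    def test_additive_over_disjoint_regions(self, clean_scene):
        img, _ = clean_scene
        lvl = integrated_intensity(img, background_roi=(0, 0))
        proj = img.data.sum(axis=0)
        roi_mean = proj[0:10, 0:10].mean()
        corrected = np.clip(proj - roi_mean, 0, None)
        half = corrected[:, : proj.shape[1] // 2].sum() + corrected[:, proj.shape[1] // 2 :].sum()
        assert lvl.integrated_intensity_per_slice == pytest.approx(half / img.shape[0])

    def test_roi_outside_projection_rejected(self, clean_scene):
        img, _ = clean_scene
        with pytest.raises(ValueError, match="ROI"):
            integrated_intensity(img, background_roi=(45, 45))


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        u, p, stars = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9
        assert stars == "n.s."

    def test_disjoint_groups_u_zero_by_rank_enumeration(self):
        a, b = [1, 2, 3], [10, 11, 12]
        # exhaustive U: number of (a_i, b_j) pairs with a_i > b_j
        u_brute = sum(x > y for x, y in itertools.product(a, b)) + 0.5 * sum(
            x == y for x, y in itertools.product(a, b)
        )
        u, p, stars = compare_groups(a, b)
        assert u == u_brute == 0.0

    def test_star_mapping(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 40)
        b = rng.normal(3, 1, 40)
        _, p, stars = compare_groups(a, b)
        assert p < 0.001 and stars == "***"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_groups([1, 2], [3, 4, 5])

    def test_power_at_two_sigma_shift(self):
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, 10)
            b = rng.normal(2.0, 1.0, 10)
            _, p, _ = compare_groups(a, b)
            hits += p < 0.05
        assert hits / n_rep >= 0.90
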