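"""Generator contracts: mass balance, determinism, placement, series laws,
two-channel correlation, FRAP closed form."""
import numpy as np
import pytest
from scipy import stats

from condensate_quant import (
    PlacementError,
    SceneParams,
    ThermoSeriesSpec,
    generate_frap_series,
    generate_scene,
    generate_series,
    generate_two_channel_scene,
)


class TestGenerateScene:
    def test_degenerate_two_phase_scene_has_two_intensity_values(self, clean_params):
        params = clean_params.model_copy(
            update=dict(n_condensates=0, volume_fraction=0.0, background_level=10.0)
        )
        img, gt = generate_scene(params)
        values = np.unique(img.data)
        assert values.tolist() == [10.0, 10.0 + gt.true_c_dil]
        assert gt.true_c_dil == params.c_tot

    def test_mass_balance_closed_form(self, clean_scene):
        # phi=0.1, pc=5, c_tot=100 -> C_dil = 100/(0.1*5+0.9), C_den = 5*C_dil
        img, gt = clean_scene
        assert gt.true_c_dil == pytest.approx(100.0 / 1.4, rel=1e-12)
        assert gt.true_c_den == pytest.approx(500.0 / 1.4, rel=1e-12)
        # voxel-averaging the noiseless image recovers c_tot within
        # discretisation error
        assert img.data[gt.nucleus_mask].mean() == pytest.approx(100.0, rel=0.01)

    def test_seed_determinism(self, clean_params):
        img1, gt1 = generate_scene(clean_params)
        img2, gt2 = generate_scene(clean_params)
        np.testing.assert_array_equal(img1.data, img2.data)
        np.testing.assert_array_equal(gt1.condensate_labels, gt2.condensate_labels)

    def test_ground_truth_masks_consistent(self, clean_scene):
        _, gt = clean_scene
        assert not np.any(gt.condensate_mask & ~gt.nucleus_mask)
        assert gt.condensate_labels.max() == gt.n_condensates == gt.params.n_condensates
        phi_from_masks = gt.condensate_mask.sum() / gt.nucleus_mask.sum()
        assert phi_from_masks == pytest.approx(gt.true_volume_fraction, abs=1e-12)

    def test_volume_fraction_hits_target_within_discretisation(self, clean_scene):
        _, gt = clean_scene
        assert gt.true_volume_fraction == pytest.approx(0.1, rel=0.15)

    def test_partition_coefficient_monotonicity(self, clean_params):
        scenes = [
            generate_scene(clean_params.model_copy(update=dict(partition_coefficient=pc)))[1]
            for pc in (2.0, 5.0, 10.0)
        ]
        dens = [g.true_c_den for g in scenes]
        dils = [g.true_c_dil for g in scenes]
        assert dens == sorted(dens) and dens[0] < dens[-1]
        assert dils == sorted(dils, reverse=True) and dils[0] > dils[-1]

    def test_placement_failure_names_counts(self, clean_params):
        crowded = clean_params.model_copy(
            update=dict(n_condensates=60, volume_fraction=0.5, placement_attempts=200)
        )
        with pytest.raises(PlacementError, match=r"of 60"):
            generate_scene(crowded)

    def test_nucleus_must_fit_grid(self):
        with pytest.raises(ValueError, match="does not fit"):
            SceneParams(grid_shape=(8, 32, 32), nucleus_axes=(4.0, 4.0, 4.0))

    def test_noise_and_psf_keep_intensities_nonnegative(self, clean_params):
        params = clean_params.model_copy(
            update=dict(noise_model="gaussian", noise_sigma=30.0, psf_sigma=0.2)
        )
        img, _ = generate_scene(params)
        assert (img.data >= 0).all()


class TestGenerateSeries:
    def test_binary_mode_pins_both_phases(self):
        spec = ThermoSeriesSpec(n_images=10, mode="binary", rng_seed=3)
        gts = [gt for _, gt in generate_series(spec)]
        np.testing.assert_allclose([g.true_c_dil for g in gts], spec.c_sat, rtol=1e-12)
        np.testing.assert_allclose([g.true_c_den for g in gts], spec.c_den_binary, rtol=1e-12)

    def test_multicomponent_mode_phases_track_c_tot_linearly(self):
        spec = ThermoSeriesSpec(n_images=10, mode="multicomponent", rng_seed=3)
        gts = [gt for _, gt in generate_series(spec)]
        c_tots = np.linspace(*spec.c_tot_range, 10)
        dil = np.array([g.true_c_dil for g in gts])
        den = np.array([g.true_c_den for g in gts])
        assert stats.pearsonr(c_tots, dil).statistic == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(dil, spec.dil_intercept + spec.dil_slope * c_tots)
        np.testing.assert_allclose(den, spec.den_intercept + spec.den_slope * c_tots)
        assert all(np.diff([g.true_volume_fraction for g in gts]) > 0)

    def test_binary_below_saturation_is_all_dilute(self):
        spec = ThermoSeriesSpec(
            n_images=6, mode="binary", c_tot_range=(30.0, 90.0), rng_seed=4
        )
        out = generate_series(spec)
        c_tots = np.linspace(30.0, 90.0, 6)
        for c, (_, gt) in zip(c_tots, out):
            if c <= spec.c_sat:
                assert gt.n_condensates == 0
                assert gt.true_volume_fraction == 0.0
                assert gt.true_c_dil == pytest.approx(c)
            else:
                # phi follows the lever rule, clipped at 0
                phi = (c - spec.c_sat) / (spec.c_den_binary - spec.c_sat)
                assert gt.params.volume_fraction == pytest.approx(phi, rel=1e-9)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="c_tot_range"):
            ThermoSeriesSpec(c_tot_range=(200.0, 100.0))

    def test_images_ordered_by_increasing_c_tot(self):
        spec = ThermoSeriesSpec(n_images=5, rng_seed=0)
        gts = [gt for _, gt in generate_series(spec)]
        c = [g.params.c_tot for g in gts]
        assert c == sorted(c)


class TestTwoChannel:
    def test_identical_channels_correlate_perfectly(self, clean_params):
        ch1, ch2, _ = generate_two_channel_scene(clean_params, "identical")
        np.testing.assert_array_equal(ch1.data, ch2.data)

    def test_independent_noise_dominated_scene_has_null_correlation(self):
        # contrast-free scene: both channels are pure detector noise
        # contrast-free: the faint nucleus signal (0.1 a.u.) is buried under
        # sigma=10 detector noise, so shared geometry cannot correlate channels
        params = SceneParams(
            grid_shape=(16, 96, 96),
            nucleus_axes=(1.2, 3.0, 3.0),
            c_tot=0.1,
            partition_coefficient=1.0,
            volume_fraction=0.0,
            n_condensates=0,
            background_level=50.0,
            heterogeneity=0.0,
            background_heterogeneity=0.0,
            noise_model="gaussian",
            noise_sigma=10.0,
            rng_seed=9,
        )
        ch1, ch2, _ = generate_two_channel_scene(params, "independent")
        assert ch1.data.size >= 1e5
        r = np.corrcoef(ch1.data.ravel(), ch2.data.ravel())[0, 1]
        assert abs(r) < 0.1

    @pytest.mark.parametrize("rho", [0.8, 0.4, -0.5])
    def test_partial_mode_achieves_target_correlation(self, rho):
        params = SceneParams(rng_seed=7)
        ch1, ch2, _ = generate_two_channel_scene(params, "partial", rho=rho)
        r = np.corrcoef(ch1.data.ravel(), ch2.data.ravel())[0, 1]
        assert r == pytest.approx(rho, abs=0.05)
        assert (ch2.data >= 0).all()

    def test_partial_mode_requires_valid_rho(self, clean_params):
        with pytest.raises(ValueError, match="rho"):
            generate_two_channel_scene(clean_params, "partial", rho=1.5)


class TestFrap:
    def test_full_recovery_limit(self):
        trace = generate_frap_series(
            mobile_fraction=1.0, recovery_rate=50.0, noise_sd=0.0, n_timepoints=20
        )
        assert trace[-1] == pytest.approx(trace[0], rel=1e-6)

    def test_immobile_trace_stays_at_bleach_floor(self):
        trace = generate_frap_series(
            mobile_fraction=0.0, bleach_depth=0.8, noise_sd=0.0, pre_bleach_level=100.0
        )
        np.testing.assert_allclose(trace[5:], 20.0)

    def test_exponential_closed_form(self):
        rate, mf, depth, pre = 0.1, 0.8, 0.8, 100.0
        trace = generate_frap_series(
            n_timepoints=75,
            pre_bleach_level=pre,
            bleach_depth=depth,
            recovery_rate=rate,
            mobile_fraction=mf,
            noise_sd=0.0,
        )
        t = np.arange(70)
        expected = pre * ((1 - depth) + mf * depth * (1 - np.exp(-rate * t)))
        np.testing.assert_allclose(trace[5:], expected, rtol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_frap_series(recovery_rate=-1.0)
        with pytest.raises(ValueError):
            generate_frap_series(mobile_fraction=1.5)
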