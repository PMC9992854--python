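"""Generative model: prior sampling, spatial transform, GMM synthesis,
intensity corruption and resolution simulation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from synthbrain.synth import (
    ConfigurationError,
    GenerationPriors,
    apply_spatial_transform,
    corrupt_intensities,
    generate_denoiser_example,
    generate_training_pair,
    identity_instance,
    sample_generation_instance,
    simulate_resolution,
    synthesize_gmm_image,
)
from synthbrain.toy_anatomy import make_toy_label_map
from synthbrain.volumes import IntensityVolume, default_affine


@pytest.fixture(scope="module")
def lm():
    return make_toy_label_map((32, 32, 32), 17, seed=1)


class TestPriors:
    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="lower"):
            GenerationPriors(mu=(10.0, 5.0))

    def test_widened_contains_standard_ranges_pointwise(self):
        std = GenerationPriors()
        wide = std.widened()
        assert wide.wide_mode
        for name in ("rotation_deg", "translation_mm", "nonlin_strength_mm",
                     "bias_log_amplitude", "noise_std", "log_gamma", "spacing_mm"):
            lo_s, hi_s = getattr(std, name)
            lo_w, hi_w = getattr(wide, name)
            assert lo_w <= lo_s and hi_w >= hi_s, name

    def test_point_priors_yield_those_constants(self):
        pri = GenerationPriors(
            mu=(100.0, 100.0), sigma=(5.0, 5.0), rotation_deg=(2.0, 2.0),
            scaling=(1.1, 1.1), shearing=(0.0, 0.0), translation_mm=(3.0, 3.0),
            nonlin_strength_mm=(0.0, 0.0), nonlin_smooth_vox=(4.0, 4.0),
            bias_log_amplitude=(0.2, 0.2), bias_smooth_vox=(8.0, 8.0),
            noise_std=(1.0, 1.0), log_gamma=(0.0, 0.0), spacing_mm=(3.0, 3.0),
            iso_prob=1.0, flip_prob=0.0,
        )
        inst = sample_generation_instance(pri, seed=9, label_ids=[0, 1])
        assert inst.mu == {0: 100.0, 1: 100.0}
        assert inst.sigma == {0: 5.0, 1: 5.0}
        np.testing.assert_allclose(inst.rotation_deg, 2.0)
        np.testing.assert_allclose(inst.scaling, 1.1)
        np.testing.assert_allclose(inst.translation_mm, 3.0)
        assert inst.gamma == pytest.approx(1.0)
        np.testing.assert_allclose(inst.spacing_mm, 3.0)
        assert not inst.flip

    def test_same_seed_identical_instance(self):
        pri = GenerationPriors()
        a = sample_generation_instance(pri, 7, [0, 1, 2])
        b = sample_generation_instance(pri, 7, [0, 1, 2])
        assert a.mu == b.mu and a.sigma == b.sigma
        np.testing.assert_array_equal(a.rotation_deg, b.rotation_deg)
        np.testing.assert_array_equal(a.spacing_mm, b.spacing_mm)
        assert a.flip == b.flip

    def test_gamma_draws_uniform_ks(self):
        """1,000 log-gamma draws stay inside the prior range and pass a KS
        test against the uniform at alpha = 0.01."""
        pri = GenerationPriors()
        lo, hi = pri.log_gamma
        draws = np.array([
            np.log(sample_generation_instance(pri, s, []).gamma) for s in range(1000)
        ])
        assert draws.min() >= lo and draws.max() <= hi
        stat, p = sps.kstest(draws, sps.uniform(loc=lo, scale=hi - lo).cdf)
        assert p > 0.01


class TestSpatialTransform:
    def test_identity_instance_is_noop(self, lm):
        out = apply_spatial_transform(lm, identity_instance())
        np.testing.assert_array_equal(out.grid, lm.grid)

    def test_integer_translation_shifts_grid_exactly(self, lm):
        inst = dataclasses.replace(identity_instance(),
                                   translation_mm=np.array([2.0, 0.0, -3.0]))
        out = apply_spatial_transform(lm, inst)
        np.testing.assert_array_equal(out.grid[2:, :, :-3], lm.grid[:-2, :, 3:])

    def test_output_labels_subset_of_input(self, lm, priors):
        for seed in range(5):
            inst = sample_generation_instance(priors, seed, lm.label_ids)
            out = apply_spatial_transform(lm, inst)
            assert set(np.unique(out.grid)) <= set(np.unique(lm.grid))

    def test_flip_swaps_contralateral_labels(self, lm):
        inst = dataclasses.replace(identity_instance(), flip=True)
        out = apply_spatial_transform(lm, inst)
        by_id = {e.id: e for e in lm.labels}
        for e in lm.labels:
            if e.contralateral_id is not None:
                assert (out.grid == e.id).sum() == (lm.grid[::-1] == e.contralateral_id).sum()


class TestGMM:
    def test_degenerate_gaussian_constant_image(self, lm):
        inst = identity_instance(
            mu={int(k): 100.0 for k in lm.label_ids},
            sigma={int(k): 0.0 for k in lm.label_ids},
        )
        img = synthesize_gmm_image(lm, inst)
        np.testing.assert_array_equal(img.grid, 100.0)

    def test_per_label_means_within_clt_bound(self, lm):
        mu = {int(k): 50.0 + 10.0 * i for i, k in enumerate(lm.label_ids)}
        sigma = {int(k): 10.0 for k in lm.label_ids}
        inst = dataclasses.replace(identity_instance(mu, sigma), seed=123)
        img = synthesize_gmm_image(lm, inst)
        for k in np.unique(lm.grid):
            vals = img.grid[lm.grid == k]
            bound = 4.0 * sigma[int(k)] / np.sqrt(vals.size)
            assert abs(vals.mean() - mu[int(k)]) < bound

    def test_missing_gmm_parameters_raise(self, lm):
        inst = identity_instance(mu={0: 1.0}, sigma={0: 1.0})
        with pytest.raises(ConfigurationError, match="GMM"):
            synthesize_gmm_image(lm, inst)

    def test_determinism(self, lm):
        mu = {int(k): 50.0 for k in lm.label_ids}
        sd = {int(k): 5.0 for k in lm.label_ids}
        inst = dataclasses.replace(identity_instance(mu, sd), seed=5)
        a = synthesize_gmm_image(lm, inst)
        b = synthesize_gmm_image(lm, inst)
        np.testing.assert_array_equal(a.grid, b.grid)


class TestIntensityCorruption:
    def _img(self, seed=0):
        rng = np.random.default_rng(seed)
        return IntensityVolume(rng.uniform(0, 200, (16, 16, 16)).astype(np.float32),
                               np.ones(3), default_affine(np.ones(3)))

    def test_identity_chain_is_pure_rescale(self):
        img = self._img()
        inst = identity_instance()  # bias 0, noise 0, gamma 1
        out = corrupt_intensities(img, inst)
        lo, hi = img.grid.min(), img.grid.max()
        np.testing.assert_allclose(out.grid, (img.grid - lo) / (hi - lo), atol=1e-6)

    def test_rescale_postcondition_full_range(self):
        inst = dataclasses.replace(identity_instance(),
                                   bias_log_amplitude=0.4, noise_std=5.0, seed=3)
        out = corrupt_intensities(self._img(1), inst)
        assert out.grid.min() == pytest.approx(0.0)
        assert out.grid.max() == pytest.approx(1.0)

    def test_gamma_exponentiation_elementwise(self):
        img = self._img(2)
        base = corrupt_intensities(img, identity_instance())
        inst = dataclasses.replace(identity_instance(), gamma=2.0)
        out = corrupt_intensities(img, inst)
        np.testing.assert_allclose(out.grid, base.grid**2, atol=1e-5)

    def test_constant_image_maps_to_zeros(self):
        img = IntensityVolume(np.full((8, 8, 8), 5.0, dtype=np.float32),
                              np.ones(3), default_affine(np.ones(3)))
        out = corrupt_intensities(img, identity_instance())
        np.testing.assert_array_equal(out.grid, 0.0)


class TestResolutionSimulation:
    def _img(self):
        rng = np.random.default_rng(0)
        return IntensityVolume(rng.random((24, 24, 24), dtype=np.float32),
                               np.ones(3), default_affine(np.ones(3)))

    def test_1mm_draw_is_identity(self):
        img = self._img()
        out = simulate_resolution(img, identity_instance())
        np.testing.assert_array_equal(out.grid, img.grid)

    def test_thick_slices_reduce_variance_along_axis(self):
        grid = np.zeros((24, 24, 24), dtype=np.float32)
        grid[:, :, ::2] = 1.0  # varies only along axis 3
        img = IntensityVolume(grid, np.ones(3), default_affine(np.ones(3)))
        inst = dataclasses.replace(identity_instance(),
                                   spacing_mm=np.array([1.0, 1.0, 8.0]))
        out = simulate_resolution(img, inst)
        assert out.grid.var(axis=2).mean() < grid.var(axis=2).mean()

    def test_output_dims_and_spacing_unchanged(self):
        img = self._img()
        inst = dataclasses.replace(identity_instance(),
                                   spacing_mm=np.array([4.0, 1.0, 7.0]))
        out = simulate_resolution(img, inst)
        assert out.grid.shape == img.grid.shape
        np.testing.assert_allclose(out.spacing_mm, 1.0)

    def test_subvoxel_spacing_clamped(self):
        img = self._img()
        inst = dataclasses.replace(identity_instance(),
                                   spacing_mm=np.array([0.3, 0.3, 0.3]))
        out = simulate_resolution(img, inst)
        np.testing.assert_array_equal(out.grid, img.grid)


class TestTrainingPairs:
    def test_coarse_target_label_set(self, lm, priors):
        _, gt = generate_training_pair(lm, priors, "coarse", seed=2)
        assert set(np.unique(gt.grid)) <= {0, 1, 2, 3, 4}

    def test_pair_shares_grid_and_1mm_spacing(self, lm, priors):
        img, gt = generate_training_pair(lm, priors, "fine", seed=3)
        assert img.grid.shape == gt.grid.shape
        np.testing.assert_allclose(img.spacing_mm, 1.0)
        np.testing.assert_allclose(gt.spacing_mm, 1.0)

    def test_images_always_in_unit_interval(self, lm, priors):
        for seed in range(8):
            img, _ = generate_training_pair(lm, priors, "coarse", seed=seed)
            assert img.grid.min() >= 0.0 and img.grid.max() <= 1.0

    def test_fixed_seed_bit_identical(self, lm, priors):
        a_img, a_gt = generate_training_pair(lm, priors, "fine", seed=11)
        b_img, b_gt = generate_training_pair(lm, priors, "fine", seed=11)
        np.testing.assert_array_equal(a_img.grid, b_img.grid)
        np.testing.assert_array_equal(a_gt.grid, b_gt.grid)

    def test_collapsed_corruption_recovers_gmm_means(self, lm):
        """With corruption priors collapsed to identity, per-label image
        means recover the drawn GMM means (after the known rescale)."""
        pri = GenerationPriors(
            sigma=(5.0, 5.0), rotation_deg=(0, 0), scaling=(1, 1), shearing=(0, 0),
            translation_mm=(0, 0), nonlin_strength_mm=(0, 0),
            bias_log_amplitude=(0, 0), noise_std=(0, 0), log_gamma=(0, 0),
            spacing_mm=(1, 1), iso_prob=1.0, flip_prob=0.0,
        )
        img, gt = generate_training_pair(lm, pri, "fine", seed=4)
        # undo the min-max rescale to compare on the GMM intensity scale
        for k in np.unique(gt.grid):
            vals = img.grid[gt.grid == k]
            assert vals.std() < 0.25  # tight per-label clusters
        k_means = [img.grid[gt.grid == k].mean() for k in np.unique(gt.grid)]
        assert np.std(k_means) > 0.05  # labels remain separable


class TestDenoiserExamples:
    def test_standard_priors_rejected(self, lm, priors):
        with pytest.raises(ConfigurationError, match="wide"):
            generate_denoiser_example(lm, object(), priors, seed=0)

    def test_unfrozen_s1_rejected(self, lm, priors):
        class FakeNet:
            frozen = False

        with pytest.raises(ConfigurationError, match="frozen"):
            generate_denoiser_example(lm, FakeNet(), priors.widened(), seed=0)
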