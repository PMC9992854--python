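"""Volumetry (soft volumes, ICV), hard Dice, Cohen's d, covariate
correction and the B-spline aging model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthbrain.pipeline import SegmentationResult
from synthbrain.stats import (
    AgingModelSpec,
    VolumeReport,
    cohens_d,
    covariate_correct,
    estimate_icv,
    fit_aging_trajectory,
    hard_dice,
    soft_volumes,
)
from synthbrain.volumes import LabelEntry, LabelMap


def _result_from_soft(soft, names):
    order = tuple(range(soft.shape[0]))
    hard = np.argmax(soft, axis=0).astype(np.int32)
    labels = tuple(
        LabelEntry(i, n, "background" if i == 0 else "GM") for i, n in enumerate(names)
    )
    lm = LabelMap(hard, np.ones(3), np.eye(4), labels)
    return SegmentationResult(soft=soft, hard=lm, label_order=order)


class TestSoftVolumes:
    def test_two_voxel_arithmetic(self):
        soft = np.zeros((2, 1, 1, 2))
        soft[1] = [[[0.5, 0.25]]]
        soft[0] = 1.0 - soft[1]
        rep = soft_volumes(_result_from_soft(soft, ["background", "wm"]))
        assert rep.volumes["wm"] == pytest.approx(0.75)

    def test_total_volume_conservation(self):
        rng = np.random.default_rng(0)
        soft = rng.random((4, 6, 6, 6))
        soft /= soft.sum(axis=0, keepdims=True)
        rep = soft_volumes(_result_from_soft(soft, list("abcd")))
        assert sum(rep.volumes.values()) == pytest.approx(6**3, rel=1e-6)

    def test_hard_one_hot_gives_integer_counts(self):
        rng = np.random.default_rng(1)
        hard = rng.integers(0, 3, (5, 5, 5))
        soft = np.eye(3)[hard].transpose(3, 0, 1, 2).astype(float)
        rep = soft_volumes(_result_from_soft(soft, list("xyz")))
        for i, n in enumerate("xyz"):
            assert rep.volumes[n] == float((hard == i).sum())

    def test_unnormalized_soft_rejected(self):
        soft = np.full((2, 3, 3, 3), 0.7)
        with pytest.raises(ValueError, match="sum to 1"):
            soft_volumes(_result_from_soft(soft, ["a", "b"]))


class TestICV:
    def test_sum_over_declared_structures(self):
        rep = VolumeReport({"WM": 100.0, "GM": 200.0, "CSF": 50.0, "background": 1000.0})
        assert estimate_icv(rep, ["WM", "GM", "CSF"]) == pytest.approx(350.0)

    def test_csf_required(self):
        rep = VolumeReport({"WM": 100.0, "GM": 200.0, "CSF": 50.0})
        with pytest.raises(ValueError, match="CSF"):
            estimate_icv(rep, ["WM", "GM"])

    def test_invariant_to_wm_subdivision(self):
        a = VolumeReport({"WM": 100.0, "CSF": 50.0})
        b = VolumeReport({"WM-left": 60.0, "WM-right": 40.0, "CSF": 50.0})
        assert estimate_icv(a, ["WM", "CSF"]) == pytest.approx(
            estimate_icv(b, ["WM-left", "WM-right", "CSF"])
        )


class TestHardDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[:2] = True
        assert hard_dice(m, m) == 1.0

    def test_hand_case_half_overlap(self):
        # X = {a, b}, Y = {b, c}: dice = 2*1/(2+2) = 0.5
        x = np.array([1, 1, 0], dtype=bool)
        y = np.array([0, 1, 1], dtype=bool)
        assert hard_dice(x, y) == 0.5

    def test_disjoint_and_empty_conventions(self):
        a = np.array([1, 0], dtype=bool)
        b = np.array([0, 1], dtype=bool)
        assert hard_dice(a, b) == 0.0
        empty = np.zeros(2, dtype=bool)
        assert hard_dice(empty, empty) == 1.0  # absent in both = agreement

    def test_matches_counting_oracle_on_random_grids(self):
        """100 random 8^3 grids against an explicit voxel-count oracle."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.random((8, 8, 8)) < 0.3
            y = rng.random((8, 8, 8)) < 0.3
            inter = sum(
                1 for i in range(8) for j in range(8) for k in range(8)
                if x[i, j, k] and y[i, j, k]
            )
            expected = 1.0 if (x.sum() + y.sum()) == 0 else 2 * inter / (x.sum() + y.sum())
            assert hard_dice(x, y) == pytest.approx(expected, abs=1e-12)


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([5, 6, 7], [6, 5, 7]) == pytest.approx(0.0)

    def test_hand_case_d_equals_3(self):
        # C = {10, 12}, AD = {8, 8}: pooled s^2 = 1, d = 3
        assert cohens_d([10, 12], [8, 8]) == pytest.approx(3.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        c, a = rng.normal(5, 1, 20), rng.normal(4, 1, 20)
        assert cohens_d(c + 100, a + 100) == pytest.approx(cohens_d(c, a), rel=1e-12)

    def test_matches_formula_on_enumerated_integer_toys(self):
        """All 2-sample-per-group integer datasets with values 0..4 against
        a direct evaluation of the pooled-s formula."""
        vals = range(5)
        for c in itertools.combinations_with_replacement(vals, 2):
            for a in itertools.combinations_with_replacement(vals, 2):
                c_arr, a_arr = np.array(c, float), np.array(a, float)
                s2 = (c_arr.var(ddof=1) + a_arr.var(ddof=1)) / 2.0
                if s2 == 0:
                    continue
                expect = abs(c_arr.mean() - a_arr.mean()) / np.sqrt(s2)
                assert cohens_d(c, a) == pytest.approx(expect, abs=1e-12)

    def test_zero_pooled_variance_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert cohens_d([1, 1], [2, 2]) == float("inf")

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohens_d([1.0], [2.0, 3.0])


class TestCovariateCorrect:
    def test_volumes_linear_in_icv_become_constant(self):
        rng = np.random.default_rng(0)
        icv = rng.uniform(1200, 1600, 50)
        vols = 0.1 * icv + 5.0
        out = covariate_correct(vols, {"icv": icv})
        np.testing.assert_allclose(out, vols.mean(), rtol=1e-9)

    def test_zero_variance_covariate_named(self):
        with pytest.raises(ValueError, match="gender"):
            covariate_correct(np.arange(10.0), {"gender": np.ones(10)})

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(3)
        n = 200
        cov = {
            "age": rng.uniform(20, 90, n),
            "gender": rng.integers(0, 2, n).astype(float),
            "icv": rng.uniform(1200, 1700, n),
        }
        vols = 2.0 * cov["age"] - 30 * cov["gender"] + 0.05 * cov["icv"] + rng.normal(0, 5, n)
        out = covariate_correct(vols, cov)
        centred = out - out.mean()
        for c in cov.values():
            r = np.corrcoef(centred, c)[0, 1]
            assert abs(r) < 1e-10


def _simulate_aging(n, sigma, seed, gender_coef=-4.0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 90, n)
    gender = rng.integers(0, 2, n).astype(float)
    spacing = np.column_stack([
        rng.uniform(1, 7, n), rng.uniform(1, 7, n), rng.uniform(1, 7, n)
    ])
    truth = lambda a: 8.0 - 0.02 * (a - 20) - 0.0015 * (a - 55) ** 2 / 10
    spacing_coef = np.array([0.05, -0.03, 0.02])
    y = truth(ages) + gender_coef * gender + spacing @ spacing_coef
    y = y + rng.normal(0, sigma, n)
    ref = lambda a: truth(a) + spacing_coef @ np.ones(3)  # gender 0, 1 mm iso
    return ages, y, gender, spacing, ref


class TestAgingModel:
    def test_ten_equally_spaced_knots(self):
        ages, y, g, sp, _ = _simulate_aging(300, 0.1, 0)
        spec = fit_aging_trajectory(ages, y, g, sp)
        interior = spec.knots[AgingModelSpec.DEGREE:-AgingModelSpec.DEGREE]
        assert interior.size == 10
        np.testing.assert_allclose(np.diff(interior), np.diff(interior)[0], rtol=1e-9)

    def test_noise_free_data_interpolated(self):
        ages, y, g, sp, _ = _simulate_aging(400, 0.0, 1)
        spec = fit_aging_trajectory(ages, y, g, sp)
        resid = spec.design(ages, g, sp) @ np.concatenate(
            [spec.spline_coef, [spec.gender_coef], spec.spacing_coef]
        ) - y
        assert float(resid @ resid) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1])
    def test_known_spline_recovery(self, seed):
        """Trajectory RMSE < sigma/2 and gender coefficient within 10% on
        data simulated from the model (n = 2,000)."""
        sigma = 0.25
        ages, y, g, sp, ref = _simulate_aging(2000, sigma, seed)
        spec = fit_aging_trajectory(ages, y, g, sp)
        grid = np.linspace(ages.min() + 1, ages.max() - 1, 60)
        rmse = np.sqrt(np.mean((spec.predict(grid) - ref(grid)) ** 2))
        assert rmse < sigma / 2
        assert spec.gender_coef == pytest.approx(-4.0, rel=0.10)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="50"):
            fit_aging_trajectory([30] * 10, [1] * 10, [0] * 10, [[1, 1, 1]] * 10)

    def test_degenerate_age_range_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            fit_aging_trajectory([40.0] * 60, [1.0] * 60, [0] * 60, [[1, 1, 1]] * 60)
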