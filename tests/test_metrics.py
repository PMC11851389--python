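"""Metric correctness against independent brute-force loop oracles."""

import math

import numpy as np
import pytest

from scdiff.errors import ContractError
from scdiff.metrics import (
    MetricRecord,
    evaluate_pairs,
    line_profile,
    mae,
    psnr,
    roi_stats,
    rmse,
    ssim,
)


def brute_mae(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += abs(a[i, j] - b[i, j])
    return total / a.size


def brute_rmse(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return math.sqrt(total / a.size)


def brute_psnr(a, b, maxv):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return 10 * math.log10(maxv**2 / (total / a.size))


def brute_global_ssim(a, b, L):
    n = a.size
    mu_a = sum(a.flat) / n
    mu_b = sum(b.flat) / n
    var_a = sum((v - mu_a) ** 2 for v in a.flat) / n
    var_b = sum((v - mu_b) ** 2 for v in b.flat) / n
    cov = sum((x - mu_a) * (y - mu_b) for x, y in zip(a.flat, b.flat)) / n
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )


class TestClosedForms:
    def test_identical_arrays(self):
        a = np.random.default_rng(0).normal(size=(8, 8))
        assert mae(a, a) == 0.0
        assert rmse(a, a) == 0.0
        assert psnr(a, a) == float("inf")
        assert ssim(a, a) == pytest.approx(1.0)

    def test_constant_offset(self):
        a = np.zeros((4, 4))
        b = a + 50.0
        assert mae(a, b) == pytest.approx(50.0)
        assert rmse(a, b) == pytest.approx(50.0)

    def test_two_pixel_hand_case(self):
        a, b = np.array([[0.0, 0.0]]), np.array([[0.0, 10.0]])
        assert mae(a, b) == pytest.approx(5.0)
        assert rmse(a, b) == pytest.approx(math.sqrt(50.0))

    def test_psnr_log_identities(self):
        a = np.zeros((2, 2))
        assert psnr(a, a + 2000.0, 2000.0) == pytest.approx(0.0)
        assert psnr(a, a + 200.0, 2000.0) == pytest.approx(20.0)

    def test_anticorrelated_global_ssim_is_negative(self):
        a = np.array([[1.0, -1.0], [2.0, -2.0]])
        assert ssim(a, -a, 4.0) < 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(10))
    def test_all_metrics_match_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = rng.uniform(-1000, 1000, (16, 16))
        b = a + rng.normal(0, 50, (16, 16))
        assert mae(a, b) == pytest.approx(brute_mae(a, b), abs=1e-9)
        assert rmse(a, b) == pytest.approx(brute_rmse(a, b), abs=1e-9)
        assert psnr(a, b, 2000) == pytest.approx(brute_psnr(a, b, 2000), abs=1e-9)
        assert ssim(a, b, 2000) == pytest.approx(
            brute_global_ssim(a, b, 2000), abs=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_mae_never_exceeds_rmse(self, trial):
        rng = np.random.default_rng(trial)
        a = rng.normal(size=(12, 12))
        b = rng.normal(size=(12, 12))
        assert mae(a, b) <= rmse(a, b) + 1e-12

    def test_psnr_decreases_with_mse(self):
        a = np.zeros((8, 8))
        noises = [10.0, 50.0, 200.0]
        values = [psnr(a, a + n) for n in noises]
        assert values[0] > values[1] > values[2]


class TestProfilesAndRois:
    def test_constant_image_profile(self):
        img = np.full((32, 32), 100.0)
        assert np.all(line_profile(img, "row", 5) == 100.0)
        assert len(line_profile(img, "row", 120 % 32)) == 32

    def test_profile_of_clean_reconstruction_tracks_phantom(
            self, fixture_phantom_128, full_view_geometry):
        """Along the standard overlay rows, an artifact-free FBP profile
        stays within the reconstruction error budget of the ground truth."""
        from scdiff.phantom import fbp_reconstruct, radon_project

        rec = fbp_reconstruct(
            radon_project(fixture_phantom_128, full_view_geometry),
            full_view_geometry, 128)
        for row in (115, 120):
            diff = (line_profile(rec, "row", row)
                    - line_profile(fixture_phantom_128, "row", row))
            assert np.sqrt(np.mean(diff**2)) < 40.0

    def test_windowed_ssim_mode(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-1000, 1000, (32, 32))
        assert ssim(a, a, mode="windowed") == pytest.approx(1.0)
        b = a + rng.normal(0, 100, a.shape)
        assert -1.0 <= ssim(a, b, mode="windowed") <= 1.0

    def test_out_of_bounds_profile(self):
        with pytest.raises(ContractError):
            line_profile(np.zeros((8, 8)), "row", 8)

    def test_roi_constant_region(self):
        img = np.full((16, 16), 100.0)
        st = roi_stats(img, (2, 6, 2, 6))
        assert st["mean"] == pytest.approx(100.0)
        assert st["sd"] == 0.0
        assert st["n"] == 16

    def test_whole_image_roi_equals_global(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(10, 10))
        st = roi_stats(img, (0, 10, 0, 10))
        assert st["mean"] == pytest.approx(img.mean())
        assert st["sd"] == pytest.approx(img.std())

    def test_two_level_phantom_roi_means(self):
        img = np.full((20, 20), -1000.0)
        img[2:8, 2:8] = 40.0
        assert roi_stats(img, (2, 8, 2, 8))["mean"] == pytest.approx(40.0)
        assert roi_stats(img, (12, 18, 12, 18))["mean"] == pytest.approx(-1000.0)


class TestEvaluatePairs:
    def test_perfect_predictions(self):
        imgs = [np.random.default_rng(i).normal(size=(8, 8)) for i in range(3)]
        df = evaluate_pairs(imgs, [i.copy() for i in imgs])
        row = df[df.subject_id == "all"].iloc[0]
        assert row.mae == 0.0 and row.rmse == 0.0 and row.ssim == pytest.approx(1.0)

    def test_mean_row_is_arithmetic_mean(self):
        rng = np.random.default_rng(5)
        refs = [rng.uniform(-500, 500, (8, 8)) for _ in range(4)]
        preds = [r + rng.normal(0, 30, (8, 8)) for r in refs]
        df = evaluate_pairs(preds, refs, subject_ids=["a", "a", "b", "b"])
        body = df[df.subject_id != "mean"]
        mean = df[df.subject_id == "mean"].iloc[0]
        for col in ("mae", "rmse", "psnr", "ssim"):
            assert mean[col] == pytest.approx(body[col].mean(), abs=1e-9)

    def test_record_invariants_enforced(self):
        with pytest.raises(ContractError):
            MetricRecord("x", mae=10.0, rmse=5.0, psnr=30.0, ssim=0.9, n_slices=1)
        with pytest.raises(ContractError):
            MetricRecord("x", mae=1.0, rmse=5.0, psnr=30.0, ssim=1.5, n_slices=1)
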