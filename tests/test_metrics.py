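"""Fidelity and realism metrics, with analytic / Monte-Carlo oracles."""

import numpy as np
import pytest

from mmphantom import metrics as me
from mmphantom.modality import ModalityVolume, inject_textured_noise


class TestMae:
    def test_identical_volumes_give_zero(self, rng):
        a = rng.normal(size=(4, 4, 4))
        assert me.mae(a, a) == 0.0

    def test_constant_foreground_offset(self, rng):
        a = rng.normal(size=(4, 4, 4))
        background = np.zeros_like(a, dtype=bool)
        background[0] = True
        b = a.copy()
        b[~background] += 3.5
        b[background] += 100.0  # background excluded, must not matter
        assert me.mae(a, b, background) == pytest.approx(3.5)

    def test_counting_oracle_random_pair(self, rng):
        a = rng.normal(size=(4, 4, 4))
        b = rng.normal(size=(4, 4, 4))
        brute = sum(abs(x - y) for x, y in zip(a.ravel(), b.ravel())) / 64
        assert me.mae(a, b) == pytest.approx(brute)

    def test_all_background_mask_rejected(self, rng):
        a = rng.normal(size=(2, 2, 2))
        with pytest.raises(ValueError):
            me.mae(a, a, np.ones_like(a, dtype=bool))


class TestSsimFsim:
    def test_identical_images_score_one(self, rng):
        a = rng.normal(size=(2, 32, 32))
        assert me.ssim(a, a) == pytest.approx(1.0)
        assert me.fsim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_ssim_near_zero(self, rng):
        a = rng.normal(size=(1, 64, 64))
        b = rng.normal(size=(1, 64, 64))
        assert abs(me.ssim(a, b)) < 0.1

    def test_ssim_symmetric(self, rng):
        a = rng.normal(size=(1, 32, 32))
        b = a + rng.normal(scale=0.3, size=a.shape)
        assert me.ssim(a, b) == pytest.approx(me.ssim(b, a))

    def test_degradation_ranks_below_identity(self, rng):
        base = np.kron(rng.uniform(size=(1, 8, 8)), np.ones((1, 8, 8)))
        blurred = base + rng.normal(scale=0.2, size=base.shape)
        assert me.fsim(base, blurred) < 1.0
        assert 0.0 <= me.fsim(base, blurred) <= 1.0


class TestEdgeRatios:
    def _stripes(self):
        img = np.zeros((1, 48, 48))
        img[:, :, 16:32] = 1.0
        return img

    def test_identical_images_epr_one_egr_zero(self):
        img = self._stripes()
        epr, egr = me.edge_ratios(img, img)
        assert epr == 1.0 and egr == 0.0

    def test_constant_test_image_epr_zero(self):
        img = self._stripes()
        epr, _ = me.edge_ratios(img, np.zeros_like(img))
        assert epr == 0.0

    def test_grid_pattern_counting_oracle(self):
        # reference has vertical edges only; test adds horizontal ones too
        ref = self._stripes()
        test = ref.copy()
        test[:, 16:32, :] += 2.0
        from skimage.feature import canny

        e_ref = canny(ref[0], sigma=2.0)
        e_test = canny(test[0], sigma=2.0)
        epr, egr = me.edge_ratios(ref, test)
        assert epr == pytest.approx((e_ref & e_test).sum() / e_ref.sum())
        assert egr == pytest.approx((e_test & ~e_ref).sum() / e_ref.sum())
        assert egr > 0

    def test_edgeless_reference_rejected(self):
        with pytest.raises(ValueError):
            me.edge_ratios(np.zeros((1, 16, 16)), np.zeros((1, 16, 16)))


class TestRadialNps:
    def test_white_noise_spectrum_is_flat(self, rng):
        vol = ModalityVolume(rng.normal(size=(24, 64, 64)), "CT", (1.0, 1.0, 1.0))
        roi = np.ones(vol.shape, dtype=bool)
        nps = me.radial_nps(vol, roi, patch_size=16, detrend_order=1)
        # Monte-Carlo flatness: all bins within 20 % of their mean
        rel = nps.power / nps.power.mean()
        assert rel.max() < 1.2 and rel.min() > 0.8

    def test_shaped_noise_recovers_shaping_profile(self, rng):
        # convolution-theorem oracle: noise filtered by H has NPS ~ |H|^2
        def hi_pass(f):
            return f / (f.max() + 1e-12) if hasattr(f, "max") else f

        vol0 = ModalityVolume(np.zeros((24, 64, 64)), "CT", (1.0, 1.0, 1.0))
        shaped = inject_textured_noise(vol0, radial_shape=lambda f: f, magnitude=1.0, seed=3)
        roi = np.ones(vol0.shape, dtype=bool)
        nps = me.radial_nps(shaped, roi, patch_size=16, detrend_order=0)
        h2 = nps.frequencies**2
        corr = np.corrcoef(nps.power, h2)[0, 1]
        assert corr > 0.95

    def test_mean_power_matches_variance_parseval(self, rng):
        # Parseval oracle: for unit-variance white noise and unit pixel area
        # the window-corrected NPS level equals the variance (= 1 var*mm^2)
        vol = ModalityVolume(rng.normal(size=(24, 64, 64)), "CT", (1.0, 1.0, 1.0))
        roi = np.ones(vol.shape, dtype=bool)
        nps = me.radial_nps(vol, roi, patch_size=16, detrend_order=-1)
        assert nps.power.mean() == pytest.approx(1.0, rel=0.25)

    def test_roi_too_small_rejected(self, rng):
        vol = ModalityVolume(rng.normal(size=(4, 16, 16)), "CT", (1.0, 1.0, 1.0))
        roi = np.zeros(vol.shape, dtype=bool)
        roi[:, :4, :4] = True
        with pytest.raises(ValueError, match="smaller patch"):
            me.radial_nps(vol, roi, patch_size=8)


class TestNpsCorrelation:
    def _nps(self, power):
        return me.RadialNps(np.linspace(0.01, 0.5, len(power)), np.asarray(power))

    def test_self_correlation_is_one(self):
        a = self._nps([1.0, 2.0, 3.0, 2.0, 1.0])
        assert me.nps_correlation(a, a) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = self._nps([1.0, 2.0, 3.0, 2.0, 1.0])
        b = self._nps([2.0, 4.0, 6.0, 4.0, 2.0])
        assert me.nps_correlation(a, b) == pytest.approx(1.0)

    def test_textbook_pearson_value(self):
        # hand oracle: r([1,2,3], [1,2,4]) = 0.98198...
        a = self._nps([1.0, 2.0, 3.0])
        b = self._nps([1.0, 2.0, 4.0])
        assert me.nps_correlation(a, b) == pytest.approx(0.981980506, abs=1e-6)

    def test_constant_spectrum_rejected(self):
        a = self._nps([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            me.nps_correlation(a, a)


class TestNoiseMagnitude:
    def test_constant_liver_gives_zero(self):
        vol = np.full((4, 4, 4), 7.0)
        mask = np.ones_like(vol, dtype=bool)
        assert me.noise_magnitude(vol, mask) == 0.0

    def test_gaussian_noise_recovers_sigma(self, rng):
        vol = 50.0 + rng.normal(scale=12.0, size=(20, 40, 40))
        mask = np.ones(vol.shape, dtype=bool)
        assert me.noise_magnitude(vol, mask) == pytest.approx(12.0, rel=0.02)

    def test_offset_invariance(self, rng):
        vol = rng.normal(size=(4, 8, 8))
        mask = np.ones(vol.shape, dtype=bool)
        assert me.noise_magnitude(vol + 100.0, mask) == pytest.approx(
            me.noise_magnitude(vol, mask)
        )

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            me.noise_magnitude(rng.normal(size=(2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestHistogramCorrelation:
    def test_identical_volumes_give_one(self, rng):
        a = rng.normal(size=(6, 16, 16))
        assert me.histogram_correlation(a, a) == pytest.approx(1.0)

    def test_same_distribution_different_sizes(self, rng):
        # resampling oracle: count normalization makes sizes irrelevant
        a = rng.normal(size=40_000)
        b = rng.normal(size=10_000)
        r = me.histogram_correlation(a.reshape(1, 200, 200), b.reshape(1, 100, 100),
                                     bins=30, range_=(-4, 4))
        assert r > 0.97

    def test_disjoint_support_is_nonpositive(self, rng):
        a = rng.uniform(0.0, 1.0, size=(1, 50, 50))
        b = rng.uniform(9.0, 10.0, size=(1, 50, 50))
        r = me.histogram_correlation(a, b, bins=20, range_=(0.0, 10.0))
        assert r <= 0.0

    def test_single_bin_histogram_rejected(self):
        a = np.zeros((1, 4, 4))
        with pytest.raises(ValueError):
            me.histogram_correlation(a, a, bins=10, range_=(-1, 1))


class TestGaussianMaeNmRatio:
    def test_converges_to_sqrt_two_over_pi(self):
        est = me.mae_nm_gaussian_ratio(n_samples=1_000_000, seed=0)
        expected = np.sqrt(2.0 / np.pi)
        # 3 Monte-Carlo standard errors of E|X| around the analytic limit
        se = 3 * np.sqrt(1 - 2 / np.pi) / np.sqrt(1_000_000)
        assert abs(est - expected) < se

    def test_sigma_independent(self):
        a = me.mae_nm_gaussian_ratio(100_000, sigma=1.0, seed=5)
        b = me.mae_nm_gaussian_ratio(100_000, sigma=250.0, seed=5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_rounds_to_point_eight(self):
        assert round(me.mae_nm_gaussian_ratio(1_000_000, seed=1), 1) == 0.8


class TestReportAssembly:
    def _cases(self, rng):
        base = rng.normal(50, 5, size=(6, 32, 32))
        base[:, 4:28, 4:28] += 40.0  # structure so edges exist
        liver = np.zeros(base.shape, dtype=bool)
        liver[:, 8:24, 8:24] = True
        background = np.zeros(base.shape, dtype=bool)
        return {
            "CT": [
                {
                    "synthetic": base,
                    "phantom": base,
                    "reference": base,
                    "background": background,
                    "liver_synth": liver,
                    "liver_ref": liver,
                }
            ]
        }

    def test_all_identity_case(self, rng):
        report = me.build_metric_report(self._cases(rng))
        row = report.loc["CT"]
        assert row["SSIM_mean"] == pytest.approx(1.0)
        assert row["FSIM_mean"] == pytest.approx(1.0, abs=1e-9)
        assert row["EPR_mean"] == 1.0
        assert row["MAE_mean"] == 0.0
        assert row["EGR_mean"] == 0.0
        assert row["NCC_mean"] == pytest.approx(1.0)
        assert row["HistCC_mean"] == pytest.approx(1.0)

    def test_row_count_matches_modalities(self, rng):
        cases = self._cases(rng)
        cases["MRI"] = cases["CT"]
        report = me.build_metric_report(cases)
        assert len(report) == 2

    def test_mean_sd_matches_direct_recomputation(self, rng):
        values = [12.0, 15.0, 9.0]
        ratios = [me.mae_nm_ratio(v, 10.0) for v in values]
        assert ratios == [1.2, 1.5, 0.9]

    def test_reference_ratio_bookkeeping(self):
        # the published full-scale summary yields ratios 2.1 / 1.3 / 1.5
        ref = me.REFERENCE_FULL_SCALE_REPORT
        ratios = {
            m: me.mae_nm_ratio(ref[m]["MAE"][0], ref[m]["NM_synthetic"][0])
            for m in ("CBCT", "CT", "MRI")
        }
        assert ratios == {"CBCT": 2.1, "CT": 1.3, "MRI": 1.5}
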