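"""CT/CBCT/MRI simulation: attenuation, HU, FOV, VIBE signal, normalization."""

import dataclasses

import numpy as np
import pytest

from mmphantom import phantom as ph
from mmphantom import modality as mo


def uniform_phantom(organ_id, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    return ph.OrganLabelVolume(np.full(shape, organ_id, dtype=np.int16), spacing)


class TestAttenuationAndHu:
    def test_background_phantom_is_air(self, property_table):
        vol = uniform_phantom(ph.BACKGROUND)
        mu = mo.attenuation_volume(vol, property_table, 100)
        assert np.allclose(mu, property_table.mu(ph.BACKGROUND, 100))
        assert mu.max() < 0.01  # ~ air

    def test_single_organ_constant_mu(self, property_table):
        vol = uniform_phantom(ph.LIVER)
        mu = mo.attenuation_volume(vol, property_table, 95)
        assert np.allclose(mu, property_table.mu(ph.LIVER, 95))

    def test_energy_off_grid_rejected(self, small_phantom, property_table):
        with pytest.raises(ValueError):
            mo.attenuation_volume(small_phantom, property_table, 97)

    def test_soft_tissue_mu_decreases_with_energy(self, property_table):
        # tabulate-and-compare oracle over the full energy grid
        mus = [property_table.mu(ph.LIVER, e) for e in mo.ENERGIES_KEV]
        assert all(a >= b for a, b in zip(mus, mus[1:]))

    @pytest.mark.parametrize(
        "mu,expected_hu", [(1.0, 0.0), (0.0, -1000.0), (2.0, 1000.0)]
    )
    def test_hu_conversion_anchors(self, mu, expected_hu):
        assert mo.mu_to_hu(np.array([mu]), 1.0)[0] == pytest.approx(expected_hu)

    def test_nonpositive_mu_water_rejected(self):
        with pytest.raises(ValueError):
            mo.mu_to_hu(np.ones(3), 0.0)

    def test_table_csv_round_trip(self, property_table, tmp_path):
        path = tmp_path / "tissues.csv"
        property_table.to_csv(path)
        loaded = mo.TissuePropertyTable.from_csv(path)
        assert loaded.organ_ids() == property_table.organ_ids()
        assert loaded.mu(ph.LIVER, 110) == pytest.approx(property_table.mu(ph.LIVER, 110))
        assert loaded.mu_water(90) == pytest.approx(property_table.mu_water(90))


class TestCbctFov:
    def test_huge_radius_keeps_everything(self, small_phantom, property_table):
        vol = mo.ct_phantom(small_phantom, property_table, 100, modality="CBCT")
        liver = ph.extract_organ_mask(small_phantom, {ph.LIVER})
        out = mo.apply_cbct_fov(vol, liver, mo.FovSpec(radius_mm=1e6))
        np.testing.assert_array_equal(out.intensities, vol.intensities)

    def test_tiny_radius_blanks_to_window_floor(self, small_phantom, property_table):
        vol = mo.ct_phantom(small_phantom, property_table, 100, modality="CBCT")
        liver = ph.extract_organ_mask(small_phantom, {ph.LIVER})
        out = mo.apply_cbct_fov(vol, liver, mo.FovSpec(radius_mm=1e-6))
        floor = mo.DEFAULT_WINDOWS["CBCT"][0]
        assert (out.intensities == floor).mean() > 0.999

    def test_retained_fraction_matches_cylinder_volume(self):
        # analytic oracle: pi r^2 / area for an in-plane disk, full z extent
        shape = (4, 64, 64)
        vol = mo.ModalityVolume(np.ones(shape), "CBCT", (1.0, 1.0, 1.0), window=(0.0, 2.0))
        liver = np.zeros(shape, dtype=bool)
        liver[:, 32, 32] = True
        radius = 20.0
        out = mo.apply_cbct_fov(vol, liver, mo.FovSpec(radius_mm=radius))
        kept = (out.intensities == 1.0).mean()
        expected = np.pi * radius**2 / (64 * 64)
        assert kept == pytest.approx(expected, rel=0.05)

    def test_empty_liver_mask_rejected(self, small_phantom, property_table):
        vol = mo.ct_phantom(small_phantom, property_table, 100, modality="CBCT")
        with pytest.raises(ValueError):
            mo.apply_cbct_fov(vol, np.zeros(vol.shape, dtype=bool))


class TestVibeSignal:
    def test_zero_flip_angle_gives_zero_signal(self):
        p = mo.VibeParameters(TR=7.25, TE=4.54, alpha=0.0)
        assert mo.vibe_signal(800.0, 34.0, 1.0, p) == 0.0

    def test_saturation_limit_rho_sin_alpha(self):
        # TR >> T1 and TE = 0 saturate the longitudinal term
        p = mo.VibeParameters(TR=1e7, TE=0.0, alpha=10.0)
        si = mo.vibe_signal(800.0, 34.0, 0.7, p)
        assert si == pytest.approx(0.7 * np.sin(np.deg2rad(10.0)), rel=1e-6)

    def test_matches_independent_scalar_evaluation(self):
        # oracle: hand evaluation of the signal equation with math.* only
        import math

        T1, T2, rho, TR, TE, alpha = 800.0, 34.0, 1.0, 7.25, 4.54, 10.0
        e1 = math.exp(-TR / T1)
        expected = (
            rho * math.sin(math.radians(alpha)) * (1 - e1)
            / (1 - math.cos(math.radians(alpha)) * e1)
            * math.exp(-TE / T2)
        )
        got = mo.vibe_signal(T1, T2, rho, mo.VibeParameters(TR, TE, alpha))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got >= 0

    def test_monotone_in_rho_and_t2(self):
        p = mo.VibeParameters()
        rhos = np.linspace(0.1, 1.0, 7)
        sis = [mo.vibe_signal(800.0, 34.0, r, p) for r in rhos]
        assert all(b >= a for a, b in zip(sis, sis[1:]))
        t2s = np.linspace(10.0, 200.0, 7)
        sis = [mo.vibe_signal(800.0, t2, 0.7, p) for t2 in t2s]
        assert all(b >= a for a, b in zip(sis, sis[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mo.VibeParameters(TR=4.0, TE=5.0)
        with pytest.raises(ValueError):
            mo.vibe_signal(-1.0, 34.0, 1.0)


class TestMriPhantom:
    def test_zero_jitter_reproduces_table_signal(self, small_phantom, property_table):
        vol = mo.mri_phantom(small_phantom, property_table, jitter_frac=0.0, seed=0)
        for organ in (ph.LIVER, ph.SPLEEN):
            T1, T2, rho = property_table.relaxation(organ)
            expected = mo.vibe_signal(T1, T2, rho)
            got = vol.intensities[small_phantom.labels == organ]
            assert np.allclose(got, expected)

    def test_seed_determinism(self, small_phantom, property_table):
        a = mo.mri_phantom(small_phantom, property_table, seed=5)
        b = mo.mri_phantom(small_phantom, property_table, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        c = mo.mri_phantom(small_phantom, property_table, seed=6)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_jittered_signal_within_extremal_envelope(self, small_phantom, property_table):
        # extremal oracle: evaluate the signal at all 8 jitter corners
        j = 0.05
        vol = mo.mri_phantom(small_phantom, property_table, jitter_frac=j, seed=11)
        for organ in (ph.LIVER, ph.KIDNEY_LEFT, ph.AORTA):
            T1, T2, rho = property_table.relaxation(organ)
            corners = [
                mo.vibe_signal(T1 * a, T2 * b, rho * c)
                for a in (1 - j, 1 + j)
                for b in (1 - j, 1 + j)
                for c in (1 - j, 1 + j)
            ]
            got = vol.intensities[small_phantom.labels == organ]
            assert got.min() >= min(corners) - 1e-12
            assert got.max() <= max(corners) + 1e-12

    def test_missing_property_names_organ(self, small_phantom, property_table):
        frame = property_table.frame[property_table.frame["organ_id"] != ph.SPLEEN]
        table = mo.TissuePropertyTable(
            frame.copy(), {e: property_table.mu_water(e) for e in mo.ENERGIES_KEV}
        )
        with pytest.raises(KeyError, match="spleen"):
            mo.mri_phantom(small_phantom, table)


class TestWindowAndNormalize:
    def test_affine_endpoints_and_midpoint(self):
        vol = mo.ModalityVolume(
            np.array([[[-1024.0, 238.0, 1500.0]]]), "CT", (1.0, 1.0, 1.0)
        )
        out = mo.window_and_normalize(vol, (-1024.0, 1500.0))
        lo, hi = -1024.0, 1500.0
        assert out.intensities[0, 0, 0] == pytest.approx(-1.0)
        assert out.intensities[0, 0, 2] == pytest.approx(1.0)
        # direct affine oracle for an interior value
        assert out.intensities[0, 0, 1] == pytest.approx((238 - lo) / (hi - lo) * 2 - 1)
        assert out.normalized

    def test_out_of_window_values_clip_to_unit(self):
        vol = mo.ModalityVolume(np.array([[[-5000.0, 5000.0]]]), "CT", (1.0, 1.0, 1.0))
        out = mo.window_and_normalize(vol, (-1024.0, 1500.0))
        assert out.intensities.min() == -1.0 and out.intensities.max() == 1.0

    def test_percentile_window_on_whole_array(self, rng):
        data = rng.normal(size=(6, 10, 10))
        vol = mo.ModalityVolume(data, "MRI", (1.0, 1.0, 1.0))
        out = mo.window_and_normalize(vol, ("percentile", 10, 90))
        lo, hi = np.percentile(data, [10, 90])
        assert out.window == (pytest.approx(lo), pytest.approx(hi))

    def test_constant_volume_percentile_rejected(self):
        vol = mo.ModalityVolume(np.zeros((3, 3, 3)), "MRI", (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            mo.window_and_normalize(vol, ("percentile", 10, 90))

    def test_order_preserving_inside_window(self, rng):
        data = np.sort(rng.uniform(-500, 1000, size=(1, 1, 50)))
        vol = mo.ModalityVolume(data, "CT", (1.0, 1.0, 1.0))
        out = mo.window_and_normalize(vol, (-1024.0, 1500.0))
        assert (np.diff(out.intensities[0, 0]) >= 0).all()


class TestTexturedNoise:
    def test_zero_magnitude_is_identity(self, rng):
        vol = mo.ModalityVolume(rng.normal(size=(4, 16, 16)), "CT", (1.0, 1.0, 1.0))
        out = mo.inject_textured_noise(vol, magnitude=0.0, seed=1)
        np.testing.assert_array_equal(out.intensities, vol.intensities)

    def test_liver_noise_std_matches_magnitude(self, rng):
        shape = (8, 48, 48)
        vol = mo.ModalityVolume(np.zeros(shape), "CT", (1.0, 1.0, 1.0))
        mask = np.zeros(shape, dtype=bool)
        mask[:, 8:40, 8:40] = True
        out = mo.inject_textured_noise(vol, magnitude=25.0, seed=2, liver_mask=mask)
        measured = out.intensities[mask].std()
        assert measured == pytest.approx(25.0, rel=0.05)

    def test_determinism(self):
        vol = mo.ModalityVolume(np.zeros((2, 16, 16)), "CT", (1.0, 1.0, 1.0))
        a = mo.inject_textured_noise(vol, magnitude=1.0, seed=9)
        b = mo.inject_textured_noise(vol, magnitude=1.0, seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestCoRegistration:
    def test_modalities_share_anatomy_voxelwise(self, small_phantom, property_table):
        """CT and MRI from one phantom instance are co-registered by construction:
        organ boundaries (intensity-constant regions) coincide exactly."""
        ct = mo.ct_phantom(small_phantom, property_table, 100)
        mri = mo.mri_phantom(small_phantom, property_table, jitter_frac=0.0)
        for organ in (ph.LIVER, ph.SPINE):
            mask = small_phantom.labels == organ
            assert np.ptp(ct.intensities[mask]) == 0
            assert np.ptp(mri.intensities[mask]) == 0
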