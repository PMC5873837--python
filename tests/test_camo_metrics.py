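"""Granularity spectra, pattern difference, luminance histograms, contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camobreak.camo_metrics import (
    GranularitySchedule,
    GranularitySpectrum,
    band_schedule,
    granularity_spectrum,
    luminance_distribution_difference,
    measure_photo,
    pattern_difference,
    patch_contrast,
)
from camobreak.imaging import LuminanceImage, simulate_dichromat
from camobreak.synthetic_data import SceneSpec, generate_scene


class TestBandSchedule:
    def test_cap_256_gives_15_bands_ending_at_256(self):
        s = band_schedule(256)
        assert len(s) == 15
        assert s.band_sizes[0] == 2.0
        assert s.band_sizes[-1] == pytest.approx(256.0, rel=1e-9)

    def test_cap_128_gives_13_bands_ending_at_128(self):
        s = band_schedule(128)
        assert len(s) == 13
        assert s.band_sizes[-1] == pytest.approx(128.0, rel=1e-9)

    def test_cap_equal_start_gives_single_band(self):
        assert band_schedule(2).band_sizes == (2.0,)

    def test_cap_below_start_rejected(self):
        with pytest.raises(ValueError):
            band_schedule(1.5)

    def test_consecutive_ratio_is_sqrt2(self):
        s = band_schedule(256).band_sizes
        ratios = np.diff(np.log(s))
        assert np.allclose(ratios, np.log(np.sqrt(2.0)), rtol=1e-9)


def _grating(wavelength, size=256, amplitude=0.4, mean=0.5):
    x = np.arange(size)
    return LuminanceImage(np.tile(mean + amplitude * np.sin(2 * np.pi * x / wavelength), (size, 1)))


class TestGranularitySpectrum:
    def test_constant_image_has_zero_energy(self):
        lum = LuminanceImage(np.full((128, 128), 0.6))
        spec = granularity_spectrum(lum, np.ones((128, 128), bool), band_schedule(64))
        assert np.allclose(spec.energies, 0.0)

    def test_pure_grating_peaks_at_its_wavelength_band(self):
        sched = band_schedule(256)
        spec = granularity_spectrum(_grating(16), np.ones((256, 256), bool), sched)
        peak = sched.band_sizes[int(np.argmax(spec.energies))]
        assert peak == pytest.approx(16.0)
        # a pure sinusoid of amplitude a has SD a/sqrt(2), all in one band
        assert spec.energies.max() == pytest.approx(0.4 / np.sqrt(2), rel=1e-6)
        off_peak = np.delete(spec.energies, int(np.argmax(spec.energies)))
        assert off_peak.max() < 1e-10

    def test_two_gratings_give_two_local_maxima(self):
        size = 256
        x = np.arange(size)
        img = LuminanceImage(
            np.tile(
                0.5
                + 0.2 * np.sin(2 * np.pi * x / 8)
                + 0.2 * np.sin(2 * np.pi * x / 64),
                (size, 1),
            )
        )
        sched = band_schedule(256)
        spec = granularity_spectrum(img, np.ones((size, size), bool), sched)
        hot = {sched.band_sizes[i] for i in np.nonzero(spec.energies > 1e-9)[0]}
        assert hot == {8.0, 64.0}

    def test_energy_invariant_to_constant_offset(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.2, 0.6, size=(128, 128))
        mask = np.ones((128, 128), bool)
        sched = band_schedule(32)
        e1 = granularity_spectrum(LuminanceImage(base), mask, sched).energies
        e2 = granularity_spectrum(LuminanceImage(base + 0.2), mask, sched).energies
        assert np.allclose(e1, e2, atol=1e-12)

    def test_doubling_contrast_doubles_energies(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0.3, 0.5, size=(128, 128))
        dev = base - base.mean()
        mask = np.ones((128, 128), bool)
        sched = band_schedule(32)
        e1 = granularity_spectrum(LuminanceImage(base.mean() + dev), mask, sched).energies
        e2 = granularity_spectrum(LuminanceImage(base.mean() + 2 * dev), mask, sched).energies
        assert np.allclose(e2, 2 * e1, rtol=1e-9)

    def test_empty_region_rejected(self):
        lum = LuminanceImage(np.full((64, 64), 0.5))
        with pytest.raises(ValueError, match="empty"):
            granularity_spectrum(lum, np.zeros((64, 64), bool), band_schedule(16))


class TestPatternDifference:
    def test_identical_spectra_give_zero(self):
        sched = band_schedule(8)
        e = np.array([0.1, 0.2, 0.3, 0.15, 0.05])
        s = GranularitySpectrum(sched, e)
        assert pattern_difference(s, s) == 0.0

    def test_unit_vectors_give_two(self):
        sched = band_schedule(8)
        a = np.zeros(5)
        a[0] = 1.0
        b = np.zeros(5)
        b[1] = 1.0
        assert pattern_difference(
            GranularitySpectrum(sched, a), GranularitySpectrum(sched, b)
        ) == pytest.approx(2.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_elementwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        sched = band_schedule(128)  # 13 bands
        e1, e2 = rng.uniform(0, 1, size=(2, 13))
        total = 0.0
        for a, b in zip(e1, e2):
            total += abs(a - b)
        got = pattern_difference(
            GranularitySpectrum(sched, e1), GranularitySpectrum(sched, e2)
        )
        assert got == pytest.approx(total, rel=1e-12)
        # symmetry and nonnegativity
        assert got >= 0.0
        assert got == pytest.approx(
            pattern_difference(
                GranularitySpectrum(sched, e2), GranularitySpectrum(sched, e1)
            )
        )

    def test_schedule_mismatch_rejected(self):
        a = GranularitySpectrum(band_schedule(8), np.zeros(5))
        b = GranularitySpectrum(band_schedule(16), np.zeros(7))
        with pytest.raises(ValueError, match="schedule"):
            pattern_difference(a, b)


class TestLuminanceDistributionDifference:
    def test_identical_sets_give_zero(self):
        px = np.array([0.1, 0.4, 0.8, 0.4])
        assert luminance_distribution_difference(px, px) == 0.0

    def test_disjoint_supports_give_one(self):
        assert luminance_distribution_difference([0.05, 0.15], [0.75, 0.85]) == 1.0

    def test_hand_enumerated_two_pixel_case(self):
        # p: half mass in bins 10 and 30; q: half mass in bins 10 and 90
        got = luminance_distribution_difference([0.105, 0.305], [0.105, 0.905])
        assert got == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounded_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, size=50)
        b = rng.uniform(0, 1, size=80)
        d = luminance_distribution_difference(t, b)
        assert 0.0 <= d <= 1.0
        assert d == luminance_distribution_difference(
            rng.permutation(t), rng.permutation(b)
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            luminance_distribution_difference([], [0.5])


class TestPatchContrast:
    def test_constant_patch_has_zero_contrast(self):
        assert patch_contrast(np.full(10, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_two_pixel_case(self):
        # population SD 0.1, mean 0.3
        assert patch_contrast([0.2, 0.4]) == pytest.approx(1.0 / 3.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        px = rng.uniform(0.1, 0.5, size=40)
        assert patch_contrast(px * 1.7) == pytest.approx(patch_contrast(px))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            patch_contrast(np.zeros(5))


class TestMeasurePhoto:
    def test_camouflaged_control_scores_near_zero(self):
        scene = generate_scene(SceneSpec(image_size=256, seed=21))
        m = measure_photo(
            scene.image, scene.target_polygon, band_schedule(64), outer_radius_px=60
        )
        mismatched = generate_scene(
            SceneSpec(image_size=256, seed=21, target_lum_offset=0.3)
        )
        m_off = measure_photo(
            mismatched.image, mismatched.target_polygon, band_schedule(64), outer_radius_px=60
        )
        assert m_off.lum_dist_diff_near > m.lum_dist_diff_near
        # a pure luminance offset leaves pattern energy roughly alike
        assert m_off.pattern_diff_near < m_off.lum_dist_diff_near

    def test_metrics_identical_across_viewing_conditions(self):
        scene = generate_scene(SceneSpec(image_size=256, seed=22))
        sched = band_schedule(64)
        m_tri = measure_photo(scene.image, scene.target_polygon, sched, outer_radius_px=60)
        m_di = measure_photo(
            simulate_dichromat(scene.image), scene.target_polygon, sched, outer_radius_px=60
        )
        assert m_tri == m_di
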