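"""Phasor FLIM-FRET: transform geometry, calibration, species fractions,
FRET trajectory, IF-guided mask ratios."""
import numpy as np
import pytest

from nanoquant import flim
from nanoquant.datatypes import DecayImage, PhasorMap
from nanoquant.simulate import (
    FLIMConfig,
    folded_decay_histogram,
    simulate_flim_image,
    simulate_reference_image,
)

FREQ = 80e6
PERIOD_NS = 1e9 / FREQ


def _expectation_map(lifetimes, fractions, n_bins=512, shape=(6, 6), photons=1000.0):
    p = folded_decay_histogram(lifetimes, fractions, n_bins, FREQ)
    hist = np.tile((photons * p)[:, None, None], (1,) + shape)
    return DecayImage(histograms=hist, bin_width_ns=PERIOD_NS / n_bins, frequency_hz=FREQ)


def _phasor_map_from_points(points, counts=100.0):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    g = pts[:, 0].reshape(n, 1)
    s = pts[:, 1].reshape(n, 1)
    return PhasorMap(
        g=g, s=s, counts=np.full((n, 1), counts), harmonic=1,
        frequency_hz=FREQ, mask=np.ones((n, 1), bool),
    )


class TestPhasorTransform:
    @pytest.mark.parametrize("tau", [0.5, 2.0, 4.04, 8.0])
    @pytest.mark.parametrize("n_bins", [512, 1024])
    def test_mono_exponential_on_universal_circle(self, tau, n_bins):
        img = _expectation_map([tau], [1.0], n_bins=n_bins)
        pm = flim.phasor_transform(img, median_passes=0)
        resid = (pm.g - 0.5) ** 2 + pm.s**2 - 0.25
        assert np.all(np.abs(resid) < 1e-6)

    def test_fluorescein_matches_closed_form(self):
        img = _expectation_map([4.04], [1.0], n_bins=1024)
        pm = flim.phasor_transform(img, median_passes=0)
        g_true, s_true = flim.lifetime_to_phasor(4.04, FREQ)
        assert abs(pm.g[0, 0] - g_true) < 1e-3
        assert abs(pm.s[0, 0] - s_true) < 1e-3

    def test_omega_tau_one_gives_half_half(self):
        tau = 1.0 / (2 * np.pi * FREQ * 1e-9)  # omega*tau = 1
        img = _expectation_map([tau], [1.0], n_bins=4096)
        pm = flim.phasor_transform(img, median_passes=0)
        assert pm.g[0, 0] == pytest.approx(0.5, abs=1e-4)
        assert pm.s[0, 0] == pytest.approx(0.5, abs=1e-4)

    def test_delta_decay_at_one_zero(self):
        hist = np.zeros((1024, 4, 4))
        hist[0] = 100.0
        img = DecayImage(histograms=hist, bin_width_ns=PERIOD_NS / 1024, frequency_hz=FREQ)
        pm = flim.phasor_transform(img, median_passes=0)
        assert pm.g[0, 0] == pytest.approx(1.0, abs=1e-4)
        assert pm.s[0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_mixture_phasor_is_weighted_mean(self):
        """Linearity checked against brute-force histogram summation."""
        pa = folded_decay_histogram([1.0], [1.0], 512, FREQ)
        pb = folded_decay_histogram([4.0], [1.0], 512, FREQ)
        w = 0.3
        hist = np.tile((1000 * (w * pa + (1 - w) * pb))[:, None, None], (1, 2, 2))
        img = DecayImage(histograms=hist, bin_width_ns=PERIOD_NS / 512, frequency_hz=FREQ)
        pm = flim.phasor_transform(img, median_passes=0)
        pma = flim.phasor_transform(_expectation_map([1.0], [1.0]), median_passes=0)
        pmb = flim.phasor_transform(_expectation_map([4.0], [1.0]), median_passes=0)
        assert pm.g[0, 0] == pytest.approx(w * pma.g[0, 0] + (1 - w) * pmb.g[0, 0], abs=1e-12)
        assert pm.s[0, 0] == pytest.approx(w * pma.s[0, 0] + (1 - w) * pmb.s[0, 0], abs=1e-12)

    def test_bi_exponential_strictly_inside_circle(self):
        img = _expectation_map([1.0, 4.0], [0.5, 0.5])
        pm = flim.phasor_transform(img, median_passes=0)
        resid = (pm.g - 0.5) ** 2 + pm.s**2 - 0.25
        assert np.all(resid < -1e-4)

    def test_zero_count_pixel_masked(self):
        hist = np.tile(
            (100 * folded_decay_histogram([4.0], [1.0], 256, FREQ))[:, None, None], (1, 3, 3)
        )
        hist[:, 1, 1] = 0.0
        img = DecayImage(histograms=hist, bin_width_ns=PERIOD_NS / 256, frequency_hz=FREQ)
        pm = flim.phasor_transform(img, median_passes=1)
        assert not pm.mask[1, 1]
        assert np.isnan(pm.g[1, 1])
        assert np.isfinite(pm.g[0, 0])


class TestCalibration:
    def test_reference_at_truth_gives_identity(self):
        ref, _ = simulate_reference_image(noise=False, n_bins=2048)
        pref = flim.phasor_transform(ref, median_passes=0)
        cal = flim.calibrate_phasor(pref, pref)
        assert cal.calibration.scale == pytest.approx(1.0, abs=1e-4)
        assert cal.calibration.rotation_rad == pytest.approx(0.0, abs=1e-4)

    def test_constructed_rotation_and_scale_recovered(self):
        ref, _ = simulate_reference_image(noise=False, n_bins=1024)
        pref = flim.phasor_transform(ref, median_passes=0)
        phi, m = 0.4, 1.7
        z = (pref.g + 1j * pref.s) * m * np.exp(1j * phi)
        from dataclasses import replace

        distorted = replace(pref, g=z.real, s=z.imag)
        cal = flim.calibrate_phasor(distorted, distorted)
        assert cal.calibration.rotation_rad == pytest.approx(-phi, abs=2e-3)
        assert cal.calibration.scale == pytest.approx(1 / m, rel=2e-3)

    def test_second_species_lands_on_circle_after_calibration(self):
        phi, m = 0.3, 1.4
        from dataclasses import replace

        def distorted(tau):
            img = _expectation_map([tau], [1.0], n_bins=1024)
            pm = flim.phasor_transform(img, median_passes=0)
            z = (pm.g + 1j * pm.s) * m * np.exp(1j * phi)
            return replace(pm, g=z.real, s=z.imag)

        ref = distorted(4.04)
        other = flim.calibrate_phasor(distorted(2.5), ref)
        g_true, s_true = flim.lifetime_to_phasor(2.5, FREQ)
        assert abs(other.g[0, 0] - g_true) < 1e-3
        assert abs(other.s[0, 0] - s_true) < 1e-3

    def test_calibration_idempotent(self):
        ref, _ = simulate_reference_image(noise=False, n_bins=1024)
        img, _ = simulate_flim_image(
            FLIMConfig(shape=(6, 6), lifetimes_ns=(2.0,), noise=False, n_bins=1024)
        )
        pref = flim.phasor_transform(ref, median_passes=0)
        pm = flim.phasor_transform(img, median_passes=0)
        once = flim.calibrate_phasor(pm, pref)
        cal_ref = flim.calibrate_phasor(pref, pref)
        twice = flim.calibrate_phasor(once, cal_ref)
        assert np.allclose(once.g, twice.g, atol=1e-9)
        assert np.allclose(once.s, twice.s, atol=1e-9)

    def test_origin_reference_rejected(self):
        pm = _phasor_map_from_points([(0.0, 0.0)])
        with pytest.raises(ValueError):
            flim.calibrate_phasor(pm, pm)


class TestTwoSpeciesFraction:
    A = (0.8, 0.3)
    B = (0.2, 0.35)

    def test_endpoints_and_midpoint(self):
        mid = tuple((np.array(self.A) + np.array(self.B)) / 2)
        pm = _phasor_map_from_points([self.A, self.B, mid])
        frac = flim.fraction_two_species(pm, self.A, self.B)
        assert np.allclose(frac.ravel(), [1.0, 0.0, 0.5], atol=1e-12)

    def test_random_cloud_equals_least_squares_oracle(self, rng):
        pts = rng.random((40, 2))
        pm = _phasor_map_from_points(pts)
        frac = flim.fraction_two_species(pm, self.A, self.B).ravel()
        a, b = np.array(self.A), np.array(self.B)
        for p, f in zip(pts, frac):
            # brute-force 1-D least squares for min_w |w a + (1-w) b - p|^2
            w = np.clip(np.dot(p - b, a - b) / np.dot(a - b, a - b), 0, 1)
            assert f == pytest.approx(w, abs=1e-12)

    def test_coincident_endpoints_rejected(self):
        pm = _phasor_map_from_points([(0.5, 0.2)])
        with pytest.raises(ValueError):
            flim.fraction_two_species(pm, self.A, self.A)


class TestFretTrajectory:
    DONOR_TAU = 2.5

    def _donor(self):
        return flim.lifetime_to_phasor(self.DONOR_TAU, FREQ)

    def test_pixel_at_donor_gives_zero_efficiency(self):
        pm = _phasor_map_from_points([self._donor()])
        fm = flim.fret_fraction_map(pm, self._donor(), background=(0.9, 0.1))
        assert fm.efficiency[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert fm.donor_tau_ns == pytest.approx(self.DONOR_TAU, rel=1e-9)

    def test_quenched_pixel_efficiency_recovered(self):
        E = 0.25
        quenched = flim.lifetime_to_phasor(self.DONOR_TAU * (1 - E), FREQ)
        pm = _phasor_map_from_points([quenched])
        fm = flim.fret_fraction_map(pm, self._donor(), background=(0.9, 0.1))
        assert fm.efficiency[0, 0] == pytest.approx(E, abs=0.01)
        assert fm.fret_positive[0, 0]

    def test_background_pixel_excluded(self):
        bg = (0.9, 0.1)
        pm = _phasor_map_from_points([bg])
        fm = flim.fret_fraction_map(pm, self._donor(), background=bg)
        assert fm.excluded[0, 0]
        assert not fm.fret_positive[0, 0]

    def test_unresolvable_donor_rejected(self):
        pm = _phasor_map_from_points([(0.5, 0.5)])
        with pytest.raises(ValueError):
            flim.fret_fraction_map(pm, (0.0, 0.0), background=(0.9, 0.1))


class TestIfMaskRatio:
    def _fret_map(self, positive):
        from nanoquant.datatypes import FretFractionMap

        positive = np.asarray(positive, dtype=bool)
        return FretFractionMap(
            efficiency=positive.astype(float) * 0.3,
            background_fraction=np.zeros_like(positive, dtype=float),
            fret_positive=positive,
            excluded=np.zeros_like(positive, dtype=bool),
            fret_cutoff=0.1,
            donor_tau_ns=2.5,
        )

    def test_uniform_field_ratio_one(self, rng):
        positive = np.ones((40, 40), bool)
        if_img = rng.random((40, 40))
        rep = flim.if_mask_ratio(self._fret_map(positive), if_img, top_percent=5)
        assert rep.ratio == pytest.approx(1.0)

    def test_constructed_two_fold_ratio(self):
        """Mask region has FRET-positive fraction 1.0, outside 0.5."""
        positive = np.zeros((40, 40), bool)
        positive[:, ::2] = True  # 50% everywhere
        positive[:5, :8] = True  # mask block fully positive
        if_img = np.zeros((40, 40))
        if_img[:5, :8] = 10.0  # top 2.5% intensities
        rep = flim.if_mask_ratio(self._fret_map(positive), if_img, top_percent=2.5)
        assert rep.fraction_inside == pytest.approx(1.0)
        assert rep.fraction_outside == pytest.approx(0.5, abs=0.02)
        assert rep.ratio == pytest.approx(2.0, abs=0.1)

    def test_full_mask_percentage_rejected(self):
        with pytest.raises(ValueError):
            flim.if_mask_ratio(self._fret_map(np.ones((8, 8), bool)), np.ones((8, 8)), top_percent=100)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            flim.if_mask_ratio(self._fret_map(np.ones((8, 8), bool)), np.ones((9, 9)))


class TestMaskRatioDirection:
    """Synthetic scenes reproducing the qualitative in-cell directions."""

    def _scene(self, mask_high_fret):
        rng = np.random.default_rng(42)
        donor = flim.lifetime_to_phasor(2.5, FREQ)
        high = flim.lifetime_to_phasor(2.5 * (1 - 0.35), FREQ)  # E = 0.35
        shape = (48, 48)
        block = np.zeros(shape, bool)
        block[16:32, 16:32] = True
        frac_high = np.where(block, 0.8 if mask_high_fret else 0.05,
                             0.05 if mask_high_fret else 0.8)
        is_high = rng.random(shape) < frac_high
        g = np.where(is_high, high[0], donor[0])
        s = np.where(is_high, high[1], donor[1])
        pm = PhasorMap(g=g, s=s, counts=np.full(shape, 100.0), harmonic=1,
                       frequency_hz=FREQ, mask=np.ones(shape, bool))
        fm = flim.fret_fraction_map(pm, donor, background=(0.98, 0.05))
        if_img = block.astype(float) + 0.01 * rng.random(shape)
        return fm, if_img

    def test_mask_on_high_fret_gives_ratio_above_one(self):
        fm, if_img = self._scene(mask_high_fret=True)
        rep = flim.if_mask_ratio(fm, if_img, top_percent=11.0)
        assert rep.ratio > 1.0

    def test_mask_on_low_fret_gives_ratio_below_one(self):
        fm, if_img = self._scene(mask_high_fret=False)
        rep = flim.if_mask_ratio(fm, if_img, top_percent=11.0)
        assert rep.ratio < 1.0
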