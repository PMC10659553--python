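"""Beer–Lambert inversion, ROI reduction and artery/vein discrimination."""

import numpy as np
import pytest

from vasoreact import spectral, synth
from vasoreact.spectral import (ExtinctionSet, RoiSet, SpectralStack,
                                hbt_percent, invert_beer_lambert, ratio_images,
                                roi_timeseries, vessel_class_hint)


def _flat_stack(value: float = 1.0, nt: int = 10, shape=(6, 6)) -> SpectralStack:
    ch = np.full((2, nt, *shape), value)
    t = np.arange(nt, dtype=float)
    return SpectralStack(channels=ch, timestamps_s=t, baseline_window_s=(0.0, 4.0))


class TestInversion:
    def test_constant_reflectance_gives_zero_changes(self, toy_extinction):
        o, r = invert_beer_lambert(_flat_stack(), toy_extinction)
        assert np.allclose(o, 0.0) and np.allclose(r, 0.0)

    def test_forward_model_round_trip_known_concentrations(self, toy_extinction):
        """Imposing (dHbO2, dHbR) = (+5, -2) through the forward model is
        recovered exactly by the inversion (L = 1, a.u.)."""
        nt, shape = 8, (5, 5)
        t = np.arange(nt, dtype=float)
        dhbo2 = np.zeros(nt)
        dhbr = np.zeros(nt)
        dhbo2[4:] = 5.0
        dhbr[4:] = -2.0
        eps = toy_extinction.matrix
        att = eps @ np.stack([dhbo2, dhbr])
        ch = np.exp(-att)[:, :, None, None] * np.ones((2, nt, *shape))
        stack = SpectralStack(channels=ch, timestamps_s=t,
                              baseline_window_s=(0.0, 3.0))
        o, r = invert_beer_lambert(stack, toy_extinction)
        assert np.max(np.abs(o[4:] - 5.0)) <= 1e-9 * 5.0
        assert np.max(np.abs(r[4:] + 2.0)) <= 1e-9 * 2.0

    def test_phantom_round_trip_to_numerical_precision(self, noiseless_phantom):
        ph, spec, ext = noiseless_phantom
        o, r = invert_beer_lambert(ph.stack, ext)
        scale = np.max(np.abs(ph.truth_dhbo2))
        assert np.max(np.abs(o - ph.truth_dhbo2)) <= 1e-9 * scale
        assert np.max(np.abs(r - ph.truth_dhbr)) <= 1e-9 * scale

    def test_inversion_linearity(self, toy_extinction):
        """Doubling the simulated concentration changes doubles the output."""
        spec1 = synth.default_dwi_phantom_spec(
            shape=(12, 12), frame_interval_s=30.0,
            amplitudes={"vein": -5.0, "artery": -4.0, "tissue": -2.0})
        spec2 = synth.default_dwi_phantom_spec(
            shape=(12, 12), frame_interval_s=30.0,
            amplitudes={"vein": -10.0, "artery": -8.0, "tissue": -4.0})
        ext = spectral.default_extinction()
        o1, r1 = invert_beer_lambert(synth.gen_dwi_stack(spec1, ext).stack, ext)
        o2, r2 = invert_beer_lambert(synth.gen_dwi_stack(spec2, ext).stack, ext)
        assert np.allclose(o2, 2 * o1, atol=1e-12)
        assert np.allclose(r2, 2 * r1, atol=1e-12)

    def test_singular_extinction_matrix_rejected(self):
        ext = ExtinctionSet(eps_hbo2_l1=1.0, eps_hbr_l1=2.0,
                            eps_hbo2_l2=2.0, eps_hbr_l2=4.0)  # proportional
        with pytest.raises(ValueError, match="singular"):
            invert_beer_lambert(_flat_stack(), ext)

    def test_nonpositive_reflectance_names_frame(self):
        ch = np.ones((2, 6, 4, 4))
        ch[1, 3, 2, 2] = 0.0
        with pytest.raises(ValueError, match="frame index 3"):
            SpectralStack(channels=ch, timestamps_s=np.arange(6.0),
                          baseline_window_s=(0.0, 2.0))

    def test_matches_independent_per_pixel_solve(self, noiseless_phantom):
        """Vectorized inversion equals an explicit 2x2 solve pixel by pixel."""
        ph, spec, ext = noiseless_phantom
        o, r = invert_beer_lambert(ph.stack, ext)
        r0 = ph.stack.baseline_reference()
        rng = np.random.default_rng(42)
        ny, nx = spec.shape
        eps = ext.matrix
        for _ in range(100):
            ti = rng.integers(0, ph.stack.timestamps_s.size)
            yi, xi = rng.integers(0, ny), rng.integers(0, nx)
            rhs = np.array([
                np.log(r0[0, yi, xi] / ph.stack.channels[0, ti, yi, xi]) / ext.path_l1,
                np.log(r0[1, yi, xi] / ph.stack.channels[1, ti, yi, xi]) / ext.path_l2,
            ])
            sol = np.linalg.solve(eps, rhs)
            assert o[ti, yi, xi] == pytest.approx(sol[0], abs=1e-12)
            assert r[ti, yi, xi] == pytest.approx(sol[1], abs=1e-12)

    def test_additivity_dhbt_equals_sum(self, noiseless_phantom):
        ph, _, _ = noiseless_phantom
        for lab in ph.truth.dhbo2:
            np.testing.assert_array_equal(
                ph.truth.dhbt(lab), ph.truth.dhbo2[lab] + ph.truth.dhbr[lab])


class TestHbtPercent:
    def test_zero_is_zero(self):
        assert np.all(hbt_percent(np.zeros(5), 1.0) == 0.0)

    def test_constant_fraction(self):
        out = hbt_percent(np.full(4, -0.1), 1.0)
        assert np.allclose(out, -10.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            hbt_percent(np.zeros(3), 0.0)

    def test_phantom_dip_depth_recovered(self):
        """A configured -16.37% artery dip reads back at the nadir."""
        spec = synth.default_dwi_phantom_spec(shape=(24, 24),
                                              frame_interval_s=5.0)
        ext = spectral.default_extinction()
        ph = synth.gen_dwi_stack(spec, ext)
        o, r = invert_beer_lambert(ph.stack, ext)
        series = roi_timeseries(o, r, ph.rois, ph.stack.timestamps_s,
                                spec.baseline_hbt)
        nadir = series.class_mean_pct("artery").min()
        assert nadir == pytest.approx(-16.37, abs=0.1)


class TestRoiTimeseries:
    def test_uniform_field(self):
        nt = 5
        field = np.full((nt, 8, 8), 3.5)
        labels = np.zeros((8, 8), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        rois = RoiSet(labels=labels, classes={1: "artery", 2: "vein"})
        s = roi_timeseries(field, np.zeros_like(field), rois, np.arange(nt))
        assert np.allclose(s.dhbo2[1], 3.5) and np.allclose(s.dhbo2[2], 3.5)

    def test_single_pixel_roi_equals_pixel_trace(self):
        rng = np.random.default_rng(1)
        field = rng.random((6, 4, 4))
        labels = np.zeros((4, 4), dtype=int)
        labels[2, 3] = 1
        rois = RoiSet(labels=labels, classes={1: "tissue"})
        s = roi_timeseries(field, field, rois, np.arange(6))
        np.testing.assert_allclose(s.dhbo2[1], field[:, 2, 3])

    def test_class_mean_is_pointwise_average(self):
        nt = 7
        f = np.zeros((nt, 6, 6))
        f[:, 0, 0] = np.sin(np.arange(nt))
        f[:, 5, 5] = np.cos(np.arange(nt))
        labels = np.zeros((6, 6), dtype=int)
        labels[0, 0] = 1
        labels[5, 5] = 2
        rois = RoiSet(labels=labels, classes={1: "artery", 2: "artery"})
        s = roi_timeseries(f, np.zeros_like(f), rois, np.arange(nt))
        expected = (f[:, 0, 0] + f[:, 5, 5]) / 2.0
        np.testing.assert_allclose(s.class_mean_pct("artery"),
                                   100 * expected, atol=1e-12)


class TestRatioImages:
    def test_baseline_time_reads_zero_change(self, noiseless_phantom):
        ph, spec, ext = noiseless_phantom
        maps = ratio_images(ph.stack, ext, [100.0],
                            baseline_hbt=spec.baseline_hbt)
        assert np.nanmax(np.abs(maps[0])) < 1e-9

    def test_all_vessel_mask_blanks_image(self, noiseless_phantom):
        ph, spec, ext = noiseless_phantom
        full = np.ones(spec.shape, dtype=bool)
        maps = ratio_images(ph.stack, ext, [100.0], vessel_mask=full,
                            baseline_hbt=spec.baseline_hbt)
        assert np.isnan(maps).all()

    def test_time_outside_record_rejected(self, noiseless_phantom):
        ph, spec, ext = noiseless_phantom
        with pytest.raises(ValueError, match="outside the record"):
            ratio_images(ph.stack, ext, [1e6])

    def test_tissue_dip_at_nadir(self, noiseless_phantom):
        """Tissue pixels at the nadir read the configured tissue dip."""
        ph, spec, ext = noiseless_phantom
        t_nadir = ph.t_inject_s + 3.0 * 60.0
        vessels = np.zeros(spec.shape, dtype=bool)
        for cls in ("artery", "vein"):
            for lab in ph.rois.labels_of(cls):
                vessels |= ph.rois.mask(lab)
        maps = ratio_images(ph.stack, ext, [t_nadir], vessel_mask=vessels,
                            baseline_hbt=spec.baseline_hbt)
        tissue_px = np.zeros(spec.shape, dtype=bool)
        for lab in ph.rois.labels_of("tissue"):
            tissue_px |= ph.rois.mask(lab)
        assert np.nanmean(maps[0][tissue_px]) == pytest.approx(-9.56, abs=0.2)


class TestVesselClassHint:
    def test_phantom_vein_scores_above_artery(self, noiseless_phantom):
        ph, _, _ = noiseless_phantom
        scores = vessel_class_hint(ph.stack, ph.rois)
        vein = np.mean([scores[l] for l in ph.rois.labels_of("vein")])
        artery = np.mean([scores[l] for l in ph.rois.labels_of("artery")])
        assert vein > artery

    def test_identical_attenuation_is_neutral(self):
        ch = np.ones((2, 6, 8, 8))
        ch[:, :, 2:4, 2:4] = 0.5  # equal darkening in both channels
        stack = SpectralStack(channels=ch, timestamps_s=np.arange(6.0),
                              baseline_window_s=(0.0, 3.0))
        labels = np.zeros((8, 8), dtype=int)
        labels[2:4, 2:4] = 1
        scores = vessel_class_hint(stack, RoiSet(labels=labels,
                                                 classes={1: "vein"}))
        assert scores[1] == pytest.approx(1.0)

    def test_no_red_attenuation_leans_arterial(self):
        ch = np.ones((2, 6, 8, 8))
        ch[0, :, 2:4, 2:4] = 0.5  # dark at 568 nm only
        stack = SpectralStack(channels=ch, timestamps_s=np.arange(6.0),
                              baseline_window_s=(0.0, 3.0))
        labels = np.zeros((8, 8), dtype=int)
        labels[2:4, 2:4] = 1
        scores = vessel_class_hint(stack, RoiSet(labels=labels,
                                                 classes={1: "artery"}))
        assert scores[1] < 1.0
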