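import numpy as np
import pytest
from scipy import signal

from csfm.dense import (
    DenseError,
    DenseSeries,
    DisplacementMaps,
    RegionMask,
    erode_region,
    filter_displacement,
    load_series,
    measure_displacement,
    phase_to_displacement,
    save_series,
    summarize_region,
    unwrap_phase,
)
from csfm.synthetic import PhantomParams, make_dense_phantom

from oracles import gaussian_disc_mean

KE = 0.6  # cycles/mm


def square_mask(shape=(48, 48), lo=8, hi=40, label=1):
    labels = np.zeros(shape, dtype=int)
    labels[lo:hi, lo:hi] = label
    return RegionMask(labels, names={label: "cerebellum"})


def series_from_phase(phase, **kw):
    phase = np.asarray(phase)
    mag = np.full_like(phase, 100.0)
    return DenseSeries(magnitude=mag, phase_ap=phase, phase_cc=np.zeros_like(phase), **kw)


class TestUnwrap:
    def test_in_range_smooth_field_unchanged(self):
        mask = square_mask()
        yy = np.linspace(-1, 1, 48)[:, None] * np.ones((1, 48))
        phase = (0.8 * yy)[None]  # well within (-pi, pi]
        out = unwrap_phase(series_from_phase(phase), mask)
        np.testing.assert_allclose(out.phase_ap, phase, atol=1e-12)

    def test_linear_ramp_spanning_3pi_recovered(self):
        mask = square_mask()
        cols = np.arange(48)[None, :] * np.ones((48, 1))
        truth = 3 * np.pi * cols / 47.0  # 0 .. 3 pi across the frame
        wrapped = np.angle(np.exp(1j * truth))
        out = unwrap_phase(series_from_phase(wrapped[None]), mask)
        region = mask.labels > 0
        # recovered up to the anchoring convention: compare gradients exactly
        # and absolute values after removing the common 2-pi multiple
        diff = out.phase_ap[0][region] - truth[region]
        assert np.ptp(diff) < 1e-6
        assert abs(np.median(diff)) % (2 * np.pi) < 1e-6

    def test_noisy_ramp_has_no_residual_jumps(self):
        rng = np.random.default_rng(7)
        mask = square_mask()
        cols = np.arange(48)[None, :] * np.ones((48, 1))
        truth = 3 * np.pi * cols / 47.0
        wrapped = np.angle(np.exp(1j * (truth + rng.normal(0, 0.2, truth.shape))))
        out = unwrap_phase(series_from_phase(wrapped[None]), mask)
        region = mask.labels > 0
        resid = out.phase_ap[0][region] - truth[region]
        resid -= 2 * np.pi * np.round(np.median(resid) / (2 * np.pi))
        assert np.abs(resid).max() < np.pi  # no 2-pi magnitude errors

    def test_tiny_region_skipped_with_warning(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[5, 5] = 1
        mask = RegionMask(labels, names={1: "cerebellum"})
        with pytest.warns(UserWarning, match="unwrap skipped"):
            unwrap_phase(series_from_phase(np.zeros((1, 16, 16))), mask)


class TestDecode:
    def test_encoding_inverse(self):
        phase = np.full((1, 20, 20), 2 * np.pi * KE * 0.1)  # encode of 0.1 mm
        maps = phase_to_displacement(series_from_phase(phase, unwrapped=True))
        np.testing.assert_allclose(maps.ap, 100.0, rtol=1e-12)

    def test_half_cycle(self):
        phase = np.full((1, 20, 20), np.pi)
        maps = phase_to_displacement(series_from_phase(phase, unwrapped=True))
        np.testing.assert_allclose(maps.ap, 1000.0 / (2 * KE), rtol=1e-12)

    def test_encode_decode_round_trip_noise_free(self):
        ph = make_dense_phantom(PhantomParams(snr=None, peak_displacement=300.0))
        series = unwrap_phase(ph.series, ph.mask)
        maps = phase_to_displacement(series, ph.mask)
        inside = ph.mask.labels > 0
        err = np.abs(maps.magnitude()[:, inside] - ph.truth_maps.magnitude()[:, inside])
        assert err.max() < 1e-3  # um


class TestFilter:
    def maps_from(self, field, validity=None):
        field = np.asarray(field, dtype=float)
        if validity is None:
            validity = np.ones(field.shape[1:], dtype=bool)
        return DisplacementMaps(
            ap=field, cc=np.zeros_like(field), validity=validity, pixel_size=0.9
        )

    def test_uniform_field_preserved(self):
        maps = self.maps_from(np.full((2, 40, 40), 200.0))
        out = filter_displacement(maps)
        np.testing.assert_allclose(out.ap, 200.0, atol=0.1)

    def test_impulse_response_matches_designed_kernel(self):
        field = np.zeros((1, 41, 41))
        field[0, 20, 20] = 1000.0
        out = filter_displacement(self.maps_from(field))
        kernel = signal.firwin(17, 0.15)
        assert out.ap[0, 20, 20] == pytest.approx(1000.0 * kernel[8] ** 2, rel=1e-9)
        assert out.ap[0].sum() == pytest.approx(1000.0, rel=5e-3)

    def test_noise_reduced_on_smooth_truth(self):
        rng = np.random.default_rng(11)
        yy, xx = np.mgrid[:48, :48]
        truth = 200.0 * np.exp(-((yy - 24) ** 2 + (xx - 24) ** 2) / (2 * 15.0**2))
        noisy = truth + rng.normal(0, 50.0, truth.shape)
        out = filter_displacement(self.maps_from(noisy[None]))
        rms_before = np.sqrt(np.mean((noisy - truth) ** 2))
        rms_after = np.sqrt(np.mean((out.ap[0] - truth) ** 2))
        assert rms_after < rms_before

    def test_never_increases_maximum_of_smooth_nonnegative_field(self):
        yy, xx = np.mgrid[:48, :48]
        field = 300.0 * np.exp(-((yy - 20) ** 2 + (xx - 28) ** 2) / (2 * 8.0**2))
        out = filter_displacement(self.maps_from(field[None]))
        assert out.ap.max() <= field.max() + 1e-9

    def test_small_map_rejected(self):
        with pytest.raises(DenseError, match="kernel"):
            filter_displacement(self.maps_from(np.zeros((1, 8, 8))))

    def test_bad_parameters_rejected(self):
        maps = self.maps_from(np.zeros((1, 40, 40)))
        with pytest.raises(DenseError):
            filter_displacement(maps, cutoff=1.5)
        with pytest.raises(DenseError):
            filter_displacement(maps, order=15)


class TestErode:
    def test_width_zero_is_identity(self):
        mask = square_mask()
        out = erode_region(mask, 0)
        np.testing.assert_array_equal(out.labels, mask.labels)

    def test_square_erosion_arithmetic(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:15, 5:15] = 1  # 10 x 10
        out = erode_region(RegionMask(labels, names={1: "cerebellum"}), 2)
        assert out.labels.sum() == 36  # 6 x 6 survives
        assert out.eroded

    def test_thin_annulus_vanishes(self):
        yy, xx = np.mgrid[:40, :40]
        r = np.hypot(yy - 20, xx - 20)
        labels = ((r >= 12) & (r < 15)).astype(int)  # ~3 voxels wide
        with pytest.raises(DenseError, match="vanishes"):
            erode_region(RegionMask(labels, names={1: "cerebellum"}), 2)


class TestSummarize:
    def test_uniform_oscillation_reports_peak(self):
        mask = square_mask()
        pulse = np.array([0.0, 0.5, 1.0, 0.4])
        field = 250.0 * pulse[:, None, None] * np.ones((1, 48, 48))
        maps = DisplacementMaps(
            ap=np.zeros_like(field), cc=field, validity=mask.labels > 0, pixel_size=0.9
        )
        s = summarize_region(maps, mask, "cerebellum")
        assert s.displacement == pytest.approx(250.0, rel=1e-12)

    def test_gaussian_bump_matches_disc_average(self):
        sigma_mm, peak, pix = 6.0, 400.0, 0.9
        mask = square_mask(shape=(64, 64), lo=4, hi=60)
        yy, xx = np.mgrid[:64, :64]
        d2 = ((yy - 32) ** 2 + (xx - 32) ** 2) * pix**2
        field = peak * np.exp(-d2 / (2 * sigma_mm**2))
        maps = DisplacementMaps(
            ap=np.zeros((1, 64, 64)), cc=field[None], validity=mask.labels > 0, pixel_size=pix
        )
        s = summarize_region(maps, mask, "cerebellum")
        ref = gaussian_disc_mean(peak, sigma_mm, np.sqrt(30.0 / np.pi))
        assert 350.0 < s.displacement < 400.0
        assert s.displacement == pytest.approx(ref, rel=0.02)

    def test_invariant_to_temporal_shift(self):
        ph = make_dense_phantom(PhantomParams(snr=None))
        maps = ph.truth_maps
        rolled = DisplacementMaps(
            ap=np.roll(maps.ap, 3, axis=0),
            cc=np.roll(maps.cc, 3, axis=0),
            validity=maps.validity,
            pixel_size=maps.pixel_size,
        )
        from csfm.dense import erode_region as er

        eroded = er(ph.mask, 2)
        a = summarize_region(maps, eroded, "cerebellum").displacement
        b = summarize_region(rolled, eroded, "cerebellum").displacement
        assert a == pytest.approx(b, rel=1e-12)

    def test_max_statistic_at_least_mean(self):
        ph = make_dense_phantom(PhantomParams(snr=None))
        eroded = erode_region(ph.mask, 2)
        mean_s = summarize_region(ph.truth_maps, eroded, "cerebellum", statistic="mean")
        max_s = summarize_region(ph.truth_maps, eroded, "cerebellum", statistic="max")
        assert max_s.displacement >= mean_s.displacement

    def test_roi_too_large_rejected(self):
        labels = np.zeros((30, 30), dtype=int)
        labels[10:14, 10:14] = 1
        mask = RegionMask(labels, names={1: "cerebellum"})
        maps = DisplacementMaps(
            ap=np.zeros((1, 30, 30)), cc=np.zeros((1, 30, 30)), validity=labels > 0, pixel_size=0.9
        )
        with pytest.raises(DenseError, match="ROI"):
            summarize_region(maps, mask, "cerebellum", roi_area=30.0)


class TestPhantomPipeline:
    def test_noise_free_uniform_recovery_exact(self):
        ph = make_dense_phantom(
            PhantomParams(snr=None, pattern="uniform", peak_displacement=100.0)
        )
        out = measure_displacement(ph.series, ph.mask, cutoff=0.15, order=16)
        assert out["cerebellum"].displacement == pytest.approx(100.0, abs=1e-3)

    def test_wrapped_phantom_needs_unwrapping(self):
        # 900 um exceeds half the encoding wavelength (833 um): decoding the
        # wrapped phase underestimates badly; unwrapping recovers it
        # encode along a single axis so the component phase exceeds pi
        ph = make_dense_phantom(
            PhantomParams(
                snr=None, pattern="uniform", peak_displacement=900.0, direction=(0.0, 1.0)
            )
        )
        naive = phase_to_displacement(ph.series, ph.mask)
        eroded = erode_region(ph.mask, 2)
        naive_disp = summarize_region(naive, eroded, "cerebellum").displacement
        good = measure_displacement(ph.series, ph.mask)["cerebellum"].displacement
        # without unwrapping the decoded displacement saturates below half an
        # encoding wavelength (1/(2 k_e) = 833 um)
        assert naive_disp < 840.0
        assert good == pytest.approx(900.0, abs=1.0)

    def test_recovery_bias_and_rms_within_phantom_accuracy(self):
        errs = []
        for seed in range(10):
            ph = make_dense_phantom(PhantomParams(snr=20.0, seed=seed))
            out = measure_displacement(ph.series, ph.mask)
            errs.append(
                out["cerebellum"].displacement
                - ph.truth_summary["cerebellum"].displacement
            )
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 5.0  # um
        assert np.sqrt((errs**2).mean()) < 13.0  # um


class TestSeriesIO:
    def test_nifti_round_trip(self, tmp_path):
        ph = make_dense_phantom(PhantomParams(seed=4))
        save_series(ph.series, tmp_path)
        back = load_series(tmp_path)
        np.testing.assert_allclose(back.phase_ap, ph.series.phase_ap, atol=1e-6)
        assert back.encoding_frequency == ph.series.encoding_frequency
        assert back.pixel_size == ph.series.pixel_size

    def test_missing_channel_named(self, tmp_path):
        ph = make_dense_phantom(PhantomParams(seed=4))
        save_series(ph.series, tmp_path)
        (tmp_path / "phase_cc.nii").unlink()
        with pytest.raises(DenseError, match="phase_cc"):
            load_series(tmp_path)

    def test_wrapped_range_validated(self):
        with pytest.raises(DenseError, match="wrapped"):
            series_from_phase(np.full((1, 8, 8), 4.0))
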