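import numpy as np
import pytest

from csfm.geometry import FluidProps
from csfm.impedance import (
    AnnularCanal,
    FlowWaveform,
    ImpedanceError,
    ImpedanceSpectrum,
    PressureTrace,
    annular_mobility,
    compute_ili,
    ili_from_geometry,
    longitudinal_impedance_from_traces,
    pressure_drop_spectrum,
    read_waveform_csv,
    reconstruct_pressure_trace,
    solve_harmonic_mobility,
    womersley_mobility_circular,
    write_waveform_csv,
)
from csfm.synthetic import make_waveform

from conftest import rasterize_disc, section_from_mask
from oracles import annulus_mobility_bvp, annulus_poiseuille_resistance, womersley_pipe_mobility

PROPS = FluidProps()


def frequency_for_alpha(alpha, radius=1.0, props=PROPS):
    return (alpha / radius) ** 2 * props.viscosity / props.density / (2 * np.pi)


class TestMobility:
    def test_poiseuille_limit(self):
        h = 0.02
        sec = section_from_mask(rasterize_disc(1.0, h), h)
        m = solve_harmonic_mobility(sec, frequency_for_alpha(0.01), PROPS)
        assert abs(m) == pytest.approx(np.pi / (8 * PROPS.viscosity), rel=0.02)

    def test_matches_womersley_closed_form(self):
        h = 0.02
        sec = section_from_mask(rasterize_disc(1.0, h), h)
        f = frequency_for_alpha(10.0)
        m = solve_harmonic_mobility(sec, f, PROPS)
        ref = womersley_pipe_mobility(1.0, f)
        assert abs(m - ref) / abs(ref) < 0.02

    def test_second_order_grid_convergence(self):
        f = frequency_for_alpha(5.0)
        ref = womersley_pipe_mobility(1.0, f)
        errs = []
        for h in (0.04, 0.02, 0.01):
            sec = section_from_mask(rasterize_disc(1.0, h), h)
            errs.append(abs(solve_harmonic_mobility(sec, f, PROPS) - ref) / abs(ref))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))
        assert orders.mean() > 1.0  # between first and second order on raster walls

    def test_annular_closed_form_vs_radial_bvp(self):
        for alpha in (1.0, 10.0, 30.0):
            f = frequency_for_alpha(alpha, radius=0.8)
            m = annular_mobility(0.5, 0.8, f, PROPS)
            ref = annulus_mobility_bvp(0.5, 0.8, f)
            assert abs(m - ref) / abs(ref) < 0.02

    def test_negative_frequency_rejected(self, disc_section):
        with pytest.raises(ImpedanceError):
            solve_harmonic_mobility(disc_section, -1.0, PROPS)


class TestSpectrum:
    def pipe_profile(self, radius=0.6, length_mm=30.0, n=7):
        # AnnularCanal with a vanishingly small core approximates a pipe only
        # poorly; use the closed-form annulus throughout instead
        z = np.linspace(0.0, length_mm, n)
        return AnnularCanal(z_mm=z, outer_radius=0.8, inner_radius=0.5)

    def test_steady_limit_is_poiseuille_series(self):
        prof = self.pipe_profile()
        spec = pressure_drop_spectrum(prof, frequencies=[0.0], segment=(0.0, 25.0))
        ref = annulus_poiseuille_resistance(0.5, 0.8, 2.5)
        assert spec.Z[0].real == pytest.approx(ref, rel=0.01)
        assert abs(spec.Z[0].imag) < 1e-9 * abs(spec.Z[0])

    def test_series_additivity(self):
        z = np.linspace(0.0, 40.0, 11)
        ri = np.where(z < 20.0, 0.45, 0.55)  # two-segment canal
        prof = AnnularCanal(z_mm=z, outer_radius=0.8, inner_radius=ri)
        for f in (0.0, 1.0, 5.0):
            z_ab = pressure_drop_spectrum(prof, frequencies=[f], segment=(0.0, 40.0)).Z[0]
            z_a = pressure_drop_spectrum(prof, frequencies=[f], segment=(0.0, 20.0)).Z[0]
            z_b = pressure_drop_spectrum(prof, frequencies=[f], segment=(20.0, 40.0)).Z[0]
            assert z_ab == pytest.approx(z_a + z_b, rel=1e-9)

    def test_shrinking_lumen_increases_impedance(self):
        z = np.linspace(0.0, 30.0, 5)
        big = AnnularCanal(z_mm=z, outer_radius=0.9, inner_radius=0.4)
        small = AnnularCanal(z_mm=z, outer_radius=0.8, inner_radius=0.5)
        for f in (0.5, 2.0, 8.0):
            zb = abs(pressure_drop_spectrum(big, frequencies=[f]).Z[0])
            zs = abs(pressure_drop_spectrum(small, frequencies=[f]).Z[0])
            assert zs > zb

    def test_scaled_pipe_steady_resistance(self):
        # scaling the cross-section radii by s scales steady Z_L by s^-4
        z = np.linspace(0.0, 30.0, 5)
        s = 0.8
        base = AnnularCanal(z_mm=z, outer_radius=0.8, inner_radius=0.5)
        scaled = AnnularCanal(z_mm=z, outer_radius=0.8 * s, inner_radius=0.5 * s)
        zb = pressure_drop_spectrum(base, frequencies=[0.0]).Z[0].real
        zs = pressure_drop_spectrum(scaled, frequencies=[0.0]).Z[0].real
        assert zs / zb == pytest.approx(s**-4, rel=0.03)

    def test_uncovered_segment_rejected(self):
        prof = self.pipe_profile(length_mm=30.0)
        with pytest.raises(ImpedanceError, match="not covered"):
            pressure_drop_spectrum(prof, frequencies=[1.0], segment=(0.0, 45.0))

    def test_waveform_supplies_harmonics(self):
        wf = make_waveform()
        spec = pressure_drop_spectrum(self.pipe_profile(), waveform=wf)
        np.testing.assert_allclose(np.diff(spec.frequencies), wf.fundamental_hz, rtol=1e-9)
        assert spec.frequencies.max() <= 9.0


class TestTraces:
    def test_proportional_traces_give_constant_resistance(self):
        wf = make_waveform(shape_seed=3)
        r0 = 7.5
        trace = PressureTrace(period=wf.period, samples=r0 * wf.samples)
        spec = longitudinal_impedance_from_traces(trace, wf)
        np.testing.assert_allclose(spec.Z, r0, rtol=1e-9)

    def test_pure_inertance_is_imaginary(self):
        period, n = 1.0, 64
        t = np.arange(n) / n * period
        q = np.sin(2 * np.pi * t)
        l_eff = 3.0
        dp = l_eff * 2 * np.pi * np.cos(2 * np.pi * t)  # L dQ/dt
        spec = longitudinal_impedance_from_traces(
            PressureTrace(period=period, samples=dp), FlowWaveform(period=period, samples=q)
        )
        z1 = spec.Z[np.argmin(abs(spec.frequencies - 1.0))]
        assert abs(z1.real) < 1e-9 * abs(z1)
        assert z1.imag == pytest.approx(2 * np.pi * 1.0 * l_eff, rel=1e-9)

    def test_round_trip_recovers_spectrum(self):
        prof = AnnularCanal(
            z_mm=np.linspace(0, 30, 7), outer_radius=0.8, inner_radius=0.5
        )
        wf = make_waveform(n_harmonics=8, shape_seed=1)
        trace = reconstruct_pressure_trace(prof, wf)
        rec = longitudinal_impedance_from_traces(trace, wf)
        gen = pressure_drop_spectrum(prof, frequencies=rec.frequencies)
        sel = rec.frequencies <= 6.5 / wf.period  # harmonics 1-6
        assert sel.sum() >= 6
        np.testing.assert_allclose(rec.Z[sel], gen.Z[sel], rtol=5e-3)

    def test_reconstructed_trace_is_real_and_zero_for_zero_flow(self):
        prof = AnnularCanal(z_mm=np.linspace(0, 30, 4), outer_radius=0.8, inner_radius=0.5)
        wf = make_waveform()
        trace = reconstruct_pressure_trace(prof, wf)
        assert np.isrealobj(trace.samples)
        zero = FlowWaveform(period=wf.period, samples=np.zeros(wf.n_samples))
        with pytest.raises(ImpedanceError):
            longitudinal_impedance_from_traces(
                PressureTrace(period=wf.period, samples=np.zeros(wf.n_samples)), zero
            )

    def test_mismatched_traces_rejected(self):
        wf = make_waveform()
        with pytest.raises(ImpedanceError, match="sampling"):
            longitudinal_impedance_from_traces(
                PressureTrace(period=wf.period, samples=np.zeros(wf.n_samples + 1)), wf
            )

    def test_single_harmonic_through_resistance_scales_sinusoid(self):
        period, n = 0.8, 64
        t = np.arange(n) / n * period
        q = 2.0 * np.sin(2 * np.pi * t / period)
        prof = AnnularCanal(z_mm=np.linspace(0, 30, 4), outer_radius=0.8, inner_radius=0.5)
        trace = reconstruct_pressure_trace(prof, FlowWaveform(period=period, samples=q))
        # single-harmonic input -> single-harmonic output (same fundamental)
        spectrum = np.abs(np.fft.rfft(trace.samples))
        assert spectrum[1] > 1e3 * max(spectrum[2:].max(), 1e-30)


class TestILI:
    def make_spectrum(self, freqs, mags):
        return ImpedanceSpectrum(frequencies=np.asarray(freqs), Z=np.asarray(mags, dtype=complex))

    def test_constant_magnitude_integrates_to_7c(self):
        c = 42.0
        spec = self.make_spectrum(np.linspace(1, 8, 29), np.full(29, c))
        assert compute_ili(spec).ili == pytest.approx(7 * c, rel=1e-12)

    def test_linear_ramp_integrates_to_31_5(self):
        f = np.linspace(1, 8, 29)
        spec = self.make_spectrum(f, f)
        assert compute_ili(spec).ili == pytest.approx(31.5, rel=1e-12)

    def test_band_not_covered_lists_frequencies(self):
        spec = self.make_spectrum([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ImpedanceError, match="8"):
            compute_ili(spec, band=(1.0, 8.0))

    def test_harmonic_sampling_interpolates_endpoints(self):
        # cardiac harmonics at 86.3 bpm start above 1 Hz; |Z| = f must still
        # integrate to ~31.5 after linear end extension
        f0 = 86.3 / 60.0
        f = f0 * np.arange(1, 7)
        spec = self.make_spectrum(f, f)
        assert compute_ili(spec).ili == pytest.approx(31.5, rel=1e-9)

    def test_ili_from_geometry_requires_enough_points(self):
        prof = AnnularCanal(z_mm=np.linspace(0, 30, 4), outer_radius=0.8, inner_radius=0.5)
        with pytest.raises(ImpedanceError):
            ili_from_geometry(prof, n_frequencies=5)

    def test_oracle_equivalence_on_annular_canal(self):
        # ILI against a finer-frequency computation built from the
        # independent radial BVP oracle (uniform slices: Z = L / M)
        prof = AnnularCanal(
            z_mm=np.linspace(0.0, 30.0, 7), outer_radius=0.8, inner_radius=0.5
        )
        ili = ili_from_geometry(prof).ili
        freqs = np.linspace(1.0, 8.0, 57)
        zl = [abs(2.5 / annulus_mobility_bvp(0.5, 0.8, f)) for f in freqs]
        ref = np.trapezoid(zl, freqs)
        assert ili == pytest.approx(ref, rel=0.02)


class TestWaveformIO:
    def test_csv_round_trip(self, tmp_path):
        wf = make_waveform(shape_seed=5)
        path = tmp_path / "wave.csv"
        write_waveform_csv(wf, path)
        back = read_waveform_csv(path)
        assert back.period == pytest.approx(wf.period, rel=1e-9)
        np.testing.assert_allclose(back.samples, wf.samples, rtol=1e-9)

    def test_waveform_invariants(self):
        with pytest.raises(ImpedanceError):
            FlowWaveform(period=1.0, samples=np.zeros(8))
        with pytest.raises(ImpedanceError):
            FlowWaveform(period=-1.0, samples=np.zeros(32))
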