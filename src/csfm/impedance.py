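"""Longitudinal impedance of oscillatory CSF flow and its 1-8 Hz integral (ILI).

Physical model
--------------
Cardiac-driven CSF flow in the cervical canal is oscillatory, low Reynolds
number, and (over the short pressure-drop segment) nearly fully developed.
Each cross-section is therefore modelled as fully developed oscillatory duct
flow: for a harmonic pressure gradient ``G e^{i w t}`` the axial velocity
solves the complex Helmholtz problem

    i w rho u = G + mu lap(u),   u = 0 on the walls,

on the slice raster.  Its integral over the lumen gives the *mobility*
``M(w) = Q/G`` (cm^3/s per dyn/cm^3).  Slices act in series, so the
longitudinal impedance of a segment [z0, z1] is the line integral

    Z_L(w) = dP(w)/Q(w) = int_{z0}^{z1} dz / M(z, w),

which is independent of the waveform (linearity).  ILI is the trapezoidal
integral of |Z_L(f)| over the 1-8 Hz band, with units dyn/cm^5.

This is a desk-scale surrogate for a transient 3D CFD simulation: it neglects
entrance/advective effects and wall motion, the regime the 3D studies
deliberately approach with long flow extensions and rigid walls.

Time-domain route
-----------------
Given measured or reconstructed traces, ``longitudinal_impedance_from_traces``
implements the spectral definition directly: DFT coefficients of the pressure
drop divided by those of the flow at the cardiac harmonics ``k/T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.special import iv, jv, kv

from .geometry import (
    MM_PER_CM,
    CanalGeometry,
    CrossSection,
    FluidProps,
    GeometryError,
)

__all__ = [
    "FlowWaveform",
    "PressureTrace",
    "ImpedanceSpectrum",
    "ILIResult",
    "AnnularCanal",
    "solve_harmonic_mobility",
    "womersley_mobility_circular",
    "annular_mobility",
    "pressure_drop_spectrum",
    "longitudinal_impedance_from_traces",
    "reconstruct_pressure_trace",
    "compute_ili",
    "ili_from_geometry",
    "read_waveform_csv",
    "write_waveform_csv",
]

#: relative floor under which a flow harmonic is considered absent
HARMONIC_FLOOR = 1e-8
#: default axial segment for the pressure drop, mm caudal from the FM
DEFAULT_SEGMENT = (0.0, 25.0)
#: default ILI band, Hz
DEFAULT_BAND = (1.0, 8.0)
#: minimum number of evaluation frequencies across the band for the
#: frequency-domain route
DEFAULT_BAND_POINTS = 29


class ImpedanceError(ValueError):
    """Raised for invalid impedance inputs (segments, traces, bands)."""


@dataclass
class FlowWaveform:
    """One cardiac cycle of volumetric CSF flow, uniformly sampled.

    ``samples`` are in cm^3/s over one period of ``period`` seconds; the
    waveform is treated as periodic.
    """

    period: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 16:
            raise ImpedanceError("waveform needs at least 16 samples")
        if self.period <= 0:
            raise ImpedanceError("period must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.period / self.n_samples

    @property
    def fundamental_hz(self) -> float:
        return 1.0 / self.period

    def harmonics(self) -> np.ndarray:
        """Positive cardiac harmonic frequencies k/T up to Nyquist."""
        return np.arange(1, self.n_samples // 2 + 1) / self.period


@dataclass
class PressureTrace:
    """Pressure drop dP(t) between the segment ends, dyn/cm^2.

    The steady (cycle-mean) component is stored separately in ``mean`` so the
    oscillatory trace in ``samples`` is zero-mean.
    """

    period: float
    samples: np.ndarray
    mean: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class ImpedanceSpectrum:
    """Complex longitudinal impedance Z_L at non-negative frequencies.

    Only f >= 0 is stored; Z_L(-f) = conj(Z_L(f)) by realness of the traces.
    Units: dyn*s/cm^5.  ``segment`` is the axial interval in mm.
    """

    frequencies: np.ndarray
    Z: np.ndarray
    segment: tuple[float, float] = DEFAULT_SEGMENT

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.Z = np.asarray(self.Z, dtype=complex)
        if self.frequencies.shape != self.Z.shape:
            raise ImpedanceError("frequencies and Z must have the same shape")
        if np.any(self.frequencies < 0):
            raise ImpedanceError("store non-negative frequencies only")
        if not np.all(np.isfinite(self.Z)):
            raise ImpedanceError("Z_L must be finite")

    def magnitude(self) -> np.ndarray:
        return np.abs(self.Z)

    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.Z))

    def to_json(self, path: str | Path, ili: "ILIResult | None" = None) -> None:
        payload = {
            "segment_mm": list(self.segment),
            "frequencies_hz": self.frequencies.tolist(),
            "zl_real": self.Z.real.tolist(),
            "zl_imag": self.Z.imag.tolist(),
        }
        if ili is not None:
            payload["ili_dyn_cm5"] = ili.ili
            payload["band_hz"] = list(ili.band)
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "zl_real": self.Z.real,
                "zl_imag": self.Z.imag,
                "zl_abs": self.magnitude(),
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ILIResult:
    """Integral of |Z_L(f)| over the band, dyn/cm^5."""

    ili: float
    band: tuple[float, float]
    evaluation_frequencies: np.ndarray

    def __post_init__(self) -> None:
        if not self.ili > 0:
            raise ImpedanceError("ILI must be positive")


@dataclass
class AnnularCanal:
    """Lightweight canal: per-slice concentric annulus radii (closed-form path).

    ``z_mm`` strictly increasing from 0; radii in cm.  Used where slice
    mobilities are wanted analytically (cohort synthesis, oracles) instead of
    through the raster Helmholtz solve.
    """

    z_mm: np.ndarray
    outer_radius: np.ndarray
    inner_radius: np.ndarray

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.outer_radius = np.broadcast_to(
            np.asarray(self.outer_radius, dtype=float), self.z_mm.shape
        ).copy()
        self.inner_radius = np.broadcast_to(
            np.asarray(self.inner_radius, dtype=float), self.z_mm.shape
        ).copy()
        if not np.all(np.diff(self.z_mm) > 0):
            raise GeometryError("z must be strictly increasing")
        if abs(self.z_mm[0]) > 1e-9:
            raise GeometryError("first slice must sit at z=0")
        if not np.all(self.outer_radius > self.inner_radius):
            raise GeometryError("outer radius must exceed inner radius")
        if not np.all(self.inner_radius >= 0):
            raise GeometryError("inner radius must be non-negative")


# ---------------------------------------------------------------------------
# Mobility solvers


def solve_harmonic_mobility(
    section: CrossSection,
    frequency: float,
    props: FluidProps = FluidProps(),
) -> complex:
    """Oscillatory-flow mobility M(w) = Q/G of one raster cross-section.

    Solves ``i w rho u - mu lap(u) = 1`` with no-slip walls by second-order
    central differences on the mask grid.  The wall is placed half a pixel
    beyond the outermost fluid pixels (the 0.5-level contour of the mask),
    using a shortened one-sided stencil there, which keeps the discrete
    boundary consistent with the sub-pixel perimeter estimate.

    Returns the complex mobility in (cm^3/s) per (dyn/cm^3).
    """
    if frequency < 0:
        raise ImpedanceError("frequency must be non-negative")
    mask = section.lumen_mask
    h = section.pixel_spacing / MM_PER_CM  # cm
    n = int(mask.sum())
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(n)

    omega = 2.0 * np.pi * frequency
    mu = props.viscosity
    rows, cols, vals = [], [], []
    diag = np.full(n, 1j * omega * props.density, dtype=complex)

    ii, jj = np.nonzero(mask)
    for axis, (di, dj) in enumerate(((1, 0), (0, 1))):
        # neighbour foreground flags on both sides; border is background by
        # the CrossSection invariant so the shifts never leave the frame
        plus_fg = mask[ii + di, jj + dj]
        minus_fg = mask[ii - di, jj - dj]
        d_plus = np.where(plus_fg, h, 0.5 * h)
        d_minus = np.where(minus_fg, h, 0.5 * h)
        denom = d_plus + d_minus
        # d2u/dx2 ~ 2*[u_m/(dm*(dm+dp)) - u_c/(dm*dp) + u_p/(dp*(dm+dp))]
        diag += mu * 2.0 / (d_plus * d_minus)
        for fg, dd, si, sj in (
            (plus_fg, d_plus, di, dj),
            (minus_fg, d_minus, -di, -dj),
        ):
            sel = np.flatnonzero(fg)
            rows.append(idx[ii[sel], jj[sel]])
            cols.append(idx[ii[sel] + si, jj[sel] + sj])
            vals.append(-mu * 2.0 / (dd[sel] * denom[sel]))

    A = sparse.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(n)]),
                np.concatenate(cols + [np.arange(n)]),
            ),
        ),
        shape=(n, n),
        dtype=complex,
    ).tocsc()
    rhs = np.ones(n, dtype=complex)
    try:
        u = spsolve(A, rhs)
    except Exception as exc:  # pragma: no cover - pathological masks
        raise ImpedanceError(
            f"Helmholtz solve failed on slice z={section.z} mm: {exc}"
        ) from exc
    if not np.all(np.isfinite(u)):
        raise ImpedanceError(f"singular Helmholtz system on slice z={section.z} mm")
    mobility = complex(np.sum(u) * h * h)
    return mobility


def womersley_mobility_circular(
    radius: float, frequency: float, props: FluidProps = FluidProps()
) -> complex:
    """Closed-form mobility of a circular pipe (Womersley solution).

    ``M = pi R^2/(i w rho) * [1 - 2 J1(L)/(L J0(L))]`` with
    ``L = i^{3/2} alpha``, ``alpha = R sqrt(w rho / mu)``.  The steady limit
    returns the Poiseuille value ``pi R^4 / (8 mu)``.
    """
    if radius <= 0:
        raise ImpedanceError("radius must be positive")
    omega = 2.0 * np.pi * frequency
    alpha = radius * np.sqrt(omega * props.density / props.viscosity)
    if alpha < 1e-4:
        return np.pi * radius**4 / (8.0 * props.viscosity)
    lam = alpha * np.exp(3j * np.pi / 4.0)
    bracket = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return np.pi * radius**2 / (1j * omega * props.density) * bracket


def annular_mobility(
    inner_radius: float,
    outer_radius: float,
    frequency: float,
    props: FluidProps = FluidProps(),
) -> complex:
    """Closed-form mobility of a concentric annulus.

    The oscillatory solution is ``u = G/(i w rho) + A I0(sr) + B K0(sr)``
    with ``s^2 = i w rho / mu`` and no-slip at both radii.  The modified
    Bessel pair is used (rather than J0/Y0 of complex argument) because I0
    grows and K0 decays across the gap; normalising each at the opposite
    wall keeps the 2x2 boundary system well conditioned at high Womersley
    number, where each wall's Stokes layer is carried by its own basis
    function.  The steady limit is annular Poiseuille:
    ``M = pi/(8 mu) [Ro^4 - Ri^4 - (Ro^2 - Ri^2)^2 / ln(Ro/Ri)]``.
    """
    if not (0 < inner_radius < outer_radius):
        raise ImpedanceError("need 0 < inner_radius < outer_radius")
    mu = props.viscosity
    omega = 2.0 * np.pi * frequency
    ri, ro = inner_radius, outer_radius
    alpha = ro * np.sqrt(omega * props.density / mu)
    if alpha < 1e-4:
        return (
            np.pi
            / (8.0 * mu)
            * (ro**4 - ri**4 - (ro**2 - ri**2) ** 2 / np.log(ro / ri))
        )
    s = np.sqrt(1j * omega * props.density / mu)  # Re(s) > 0
    up = 1.0 / (1j * omega * props.density)  # particular solution, G = 1
    # basis: Ih(r) = I0(sr)/I0(s ro), Kh(r) = K0(sr)/K0(s ri)
    Ih = lambda r: iv(0, s * r) / iv(0, s * ro)
    Kh = lambda r: kv(0, s * r) / kv(0, s * ri)
    M = np.array([[Ih(ri), 1.0], [1.0, Kh(ro)]])
    a, b = np.linalg.solve(M, np.array([-up, -up]))
    # int r I0(sr) dr = r I1(sr)/s ; int r K0(sr) dr = -r K1(sr)/s
    flow = 2.0 * np.pi * (
        up * (ro**2 - ri**2) / 2.0
        + a * (ro * iv(1, s * ro) - ri * iv(1, s * ri)) / (s * iv(0, s * ro))
        - b * (ro * kv(1, s * ro) - ri * kv(1, s * ri)) / (s * kv(0, s * ri))
    )
    return complex(flow)


# ---------------------------------------------------------------------------
# Spectrum along the canal


def _slice_inverse_mobilities(
    geometry: CanalGeometry | AnnularCanal,
    frequency: float,
    props: FluidProps,
) -> tuple[np.ndarray, np.ndarray]:
    """(z_cm, 1/M per slice) for either geometry representation."""
    if isinstance(geometry, AnnularCanal):
        z_cm = geometry.z_mm / MM_PER_CM
        inv = np.array(
            [
                1.0 / annular_mobility(ri, ro, frequency, props)
                for ri, ro in zip(geometry.inner_radius, geometry.outer_radius)
            ]
        )
    else:
        z_cm = geometry.z_mm / MM_PER_CM
        inv = np.array(
            [1.0 / solve_harmonic_mobility(s, frequency, props) for s in geometry]
        )
    return z_cm, inv


def pressure_drop_spectrum(
    geometry: CanalGeometry | AnnularCanal,
    waveform: FlowWaveform | None = None,
    props: FluidProps = FluidProps(),
    segment: tuple[float, float] = DEFAULT_SEGMENT,
    frequencies: np.ndarray | None = None,
    max_frequency: float = 9.0,
) -> ImpedanceSpectrum:
    """Longitudinal impedance spectrum Z_L(f) of a canal segment.

    ``Z_L(f) = int dz / M(z, f)`` by the trapezoid rule along z over
    ``segment`` (mm).  Frequencies are either given explicitly, or taken as
    the cardiac harmonics of ``waveform`` up to ``max_frequency``.  Because
    the model is linear and fully developed, the spectrum does not depend on
    the waveform beyond its period.
    """
    if frequencies is None:
        if waveform is None:
            raise ImpedanceError("provide either frequencies or a waveform")
        h = waveform.harmonics()
        frequencies = h[h <= max_frequency]
        if frequencies.size == 0:
            raise ImpedanceError("no cardiac harmonic below max_frequency")
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))

    z0, z1 = segment
    if not z1 > z0:
        raise ImpedanceError("segment must be increasing (z0 < z1)")
    z_all = (
        geometry.z_mm if isinstance(geometry, AnnularCanal) else geometry.z_mm
    )
    if z0 < z_all[0] - 1e-9 or z1 > z_all[-1] + 1e-9:
        raise ImpedanceError(
            f"segment [{z0}, {z1}] mm not covered by sections "
            f"spanning [{z_all[0]}, {z_all[-1]}] mm"
        )

    Z = np.empty(frequencies.shape, dtype=complex)
    for i, f in enumerate(frequencies):
        z_cm, inv = _slice_inverse_mobilities(geometry, f, props)
        # resample 1/M onto the segment, interpolating at the endpoints
        zs = np.array([z0, z1]) / MM_PER_CM
        grid = np.union1d(z_cm[(z_cm >= zs[0]) & (z_cm <= zs[1])], zs)
        inv_r = np.interp(grid, z_cm, inv.real)
        inv_i = np.interp(grid, z_cm, inv.imag)
        Z[i] = np.trapezoid(inv_r + 1j * inv_i, grid)
    return ImpedanceSpectrum(frequencies=frequencies, Z=Z, segment=(z0, z1))


def longitudinal_impedance_from_traces(
    pressure: PressureTrace,
    waveform: FlowWaveform,
    floor: float = HARMONIC_FLOOR,
) -> ImpedanceSpectrum:
    """Z_L at the cardiac harmonics from time traces (spectral definition).

    DFT coefficients of the pressure-drop trace divided elementwise by those
    of the flow trace at frequencies ``k/T``; harmonics where the flow
    coefficient magnitude falls below ``floor`` times the largest one are
    dropped rather than divided.
    """
    if pressure.samples.size != waveform.n_samples:
        raise ImpedanceError("pressure and flow traces must share the sampling grid")
    if abs(pressure.period - waveform.period) > 1e-12 * waveform.period:
        raise ImpedanceError("pressure and flow traces must share the period")
    Qk = np.fft.rfft(waveform.samples)
    Pk = np.fft.rfft(pressure.samples)
    mags = np.abs(Qk[1:])
    if mags.max() == 0:
        raise ImpedanceError("flow trace is identically zero")
    keep = 1 + np.flatnonzero(mags >= floor * mags.max())
    freqs = keep / waveform.period
    Z = Pk[keep] / Qk[keep]
    return ImpedanceSpectrum(frequencies=freqs, Z=Z)


def reconstruct_pressure_trace(
    geometry: CanalGeometry | AnnularCanal,
    waveform: FlowWaveform,
    props: FluidProps = FluidProps(),
    segment: tuple[float, float] = DEFAULT_SEGMENT,
    floor: float = HARMONIC_FLOOR,
) -> PressureTrace:
    """Synthesize the pressure-drop time trace dP(t) across the segment.

    Per-harmonic products ``Z_L(k/T) Q_k`` are inverse-Fourier synthesized
    back onto the waveform's sampling grid; harmonics with negligible flow
    content are skipped.  The steady component (from the cycle-mean flow
    through the steady resistance) is reported separately.
    """
    Qk = np.fft.rfft(waveform.samples)
    mags = np.abs(Qk[1:])
    if mags.size == 0 or mags.max() == 0:
        # zero (or constant) oscillatory flow -> zero oscillatory pressure
        mean = 0.0
        if abs(Qk[0]) > 0:
            Z0 = pressure_drop_spectrum(
                geometry, props=props, segment=segment, frequencies=[0.0]
            ).Z[0]
            mean = float((Qk[0].real / waveform.n_samples) * Z0.real)
        return PressureTrace(
            period=waveform.period,
            samples=np.zeros(waveform.n_samples),
            mean=mean,
        )
    keep = 1 + np.flatnonzero(mags >= floor * mags.max())
    freqs = keep / waveform.period
    spec = pressure_drop_spectrum(
        geometry, props=props, segment=segment, frequencies=freqs
    )
    Pk = np.zeros_like(Qk)
    Pk[keep] = spec.Z * Qk[keep]
    samples = np.fft.irfft(Pk, n=waveform.n_samples)
    mean = 0.0
    if abs(Qk[0]) > 1e-15 * (abs(Qk[0]) + mags.max()):
        Z0 = pressure_drop_spectrum(
            geometry, props=props, segment=segment, frequencies=[0.0]
        ).Z[0]
        mean = float((Qk[0].real / waveform.n_samples) * Z0.real)
    return PressureTrace(period=waveform.period, samples=samples, mean=mean)


# ---------------------------------------------------------------------------
# ILI


def compute_ili(
    spectrum: ImpedanceSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ILIResult:
    """Trapezoidal integral of |Z_L(f)| over the band (default 1-8 Hz).

    When the spectrum is sampled only at cardiac harmonics, |Z_L| is linearly
    interpolated onto the band endpoints (with linear extension when the
    fundamental lies just above the lower edge, as it does for normal heart
    rates).  Units: dyn/cm^5.
    """
    f0, f1 = band
    if not f1 > f0:
        raise ImpedanceError("band must be increasing")
    f = spectrum.frequencies
    mag = spectrum.magnitude()
    inside = (f >= f0) & (f <= f1)
    if inside.sum() < 2:
        raise ImpedanceError(
            f"need >= 2 frequencies inside the band {band}; "
            f"available: {np.round(f, 4).tolist()}"
        )
    if f.max() < f1:
        raise ImpedanceError(
            f"band upper edge {f1} Hz not covered; available up to {f.max():.4g} Hz"
        )
    order = np.argsort(f)
    fs, ms = f[order], mag[order]
    grid = np.union1d(fs[(fs > f0) & (fs < f1)], np.array([f0, f1]))
    # linear interpolation with linear end extension (fundamental may sit
    # slightly above the 1 Hz edge)
    vals = np.interp(grid, fs, ms)
    low = grid < fs[0]
    if low.any():
        slope = (ms[1] - ms[0]) / (fs[1] - fs[0])
        vals[low] = ms[0] + slope * (grid[low] - fs[0])
    ili = float(np.trapezoid(vals, grid))
    return ILIResult(ili=ili, band=(f0, f1), evaluation_frequencies=grid)


def ili_from_geometry(
    geometry: CanalGeometry | AnnularCanal,
    props: FluidProps = FluidProps(),
    segment: tuple[float, float] = DEFAULT_SEGMENT,
    band: tuple[float, float] = DEFAULT_BAND,
    n_frequencies: int = DEFAULT_BAND_POINTS,
) -> ILIResult:
    """ILI by the frequency-domain route on a uniform grid across the band."""
    if n_frequencies < DEFAULT_BAND_POINTS:
        raise ImpedanceError(
            f"use at least {DEFAULT_BAND_POINTS} evaluation frequencies"
        )
    freqs = np.linspace(band[0], band[1], n_frequencies)
    spec = pressure_drop_spectrum(
        geometry, props=props, segment=segment, frequencies=freqs
    )
    return compute_ili(spec, band=band)


# ---------------------------------------------------------------------------
# Waveform I/O


def write_waveform_csv(waveform: FlowWaveform, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": waveform.times, "flow_cm3_per_s": waveform.samples}
    ).to_csv(path, index=False)


def read_waveform_csv(path: str | Path) -> FlowWaveform:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ImpedanceError("waveform must be uniformly sampled")
    return FlowWaveform(period=float(t[-1] + dt[0]), samples=df["flow_cm3_per_s"].to_numpy())
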