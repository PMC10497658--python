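"""Decoding cardiac-induced tissue displacement from cine DENSE MRI.

DENSE (displacement encoding with stimulated echoes) writes tissue
displacement linearly into image phase: a displacement ``u`` (mm) along the
encoding direction appears as a phase ``phi = 2 pi k_e u`` (radians) at
encoding frequency ``k_e`` (cycles/mm).  Two encoded directions per frame
(anterior-posterior and cranial-caudal) give an in-plane Eulerian
displacement vector per pixel per cardiac frame.

Processing chain: spatial phase unwrapping inside each segmented brain
region (if the phase wrapped), phase-to-displacement conversion, spatial FIR
noise filtering, region erosion to drop boundary voxels, and a circular-ROI
summary: the ROI (default ~30 mm^2) is centred where the temporal peak
displacement is largest, and the reported "displacement" of a region is the
temporal maximum of the ROI's spatial-mean displacement magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal
from skimage.restoration import unwrap_phase as _unwrap2d

__all__ = [
    "DenseError",
    "DenseSeries",
    "RegionMask",
    "DisplacementMaps",
    "DisplacementSummary",
    "unwrap_phase",
    "phase_to_displacement",
    "filter_displacement",
    "erode_region",
    "summarize_region",
    "measure_displacement",
]

DEFAULT_KE = 0.6  # cycles/mm
DEFAULT_FRAME_INTERVAL = 34.0  # ms
DEFAULT_ROI_AREA = 30.0  # mm^2
DEFAULT_EROSION = 2  # voxels
DEFAULT_FIR_CUTOFF = 0.15  # normalized frequency
DEFAULT_FIR_ORDER = 16  # taps = order + 1


class DenseError(ValueError):
    """Raised for invalid DENSE series, masks or processing parameters."""


@dataclass
class DenseSeries:
    """Cine DENSE acquisition: magnitude plus two wrapped-phase channels.

    Arrays are (frames, rows, cols).  Phases are radians, wrapped to
    (-pi, pi] unless ``unwrapped`` is set.
    """

    magnitude: np.ndarray
    phase_ap: np.ndarray
    phase_cc: np.ndarray
    pixel_size: float = 0.9  # mm
    frame_interval: float = DEFAULT_FRAME_INTERVAL  # ms
    encoding_frequency: float = DEFAULT_KE  # cycles/mm
    unwrapped: bool = False

    def __post_init__(self) -> None:
        for name in ("magnitude", "phase_ap", "phase_cc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        shapes = {self.magnitude.shape, self.phase_ap.shape, self.phase_cc.shape}
        if len(shapes) != 1 or self.magnitude.ndim != 3:
            raise DenseError("magnitude and phase arrays must share a 3D shape")
        if self.encoding_frequency <= 0:
            raise DenseError("encoding frequency must be positive")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise DenseError("pixel size and frame interval must be positive")
        if not self.unwrapped:
            for name in ("phase_ap", "phase_cc"):
                p = getattr(self, name)
                if p.size and (p.min() <= -np.pi - 1e-9 or p.max() > np.pi + 1e-9):
                    raise DenseError(f"{name} must be wrapped to (-pi, pi]")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]


@dataclass
class RegionMask:
    """Integer label map over the image plane (0 = background)."""

    labels: np.ndarray
    names: dict[int, str] = field(
        default_factory=lambda: {1: "cerebellum", 2: "brainstem"}
    )
    eroded: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DenseError("labels must be 2D")

    def region(self, region: int | str) -> np.ndarray:
        return self.labels == self.label_of(region)

    def label_of(self, region: int | str) -> int:
        if isinstance(region, str):
            for k, v in self.names.items():
                if v == region:
                    return k
            raise DenseError(f"unknown region {region!r}; have {list(self.names.values())}")
        return int(region)

    def name_of(self, label: int) -> str:
        return self.names.get(label, str(label))


@dataclass
class DisplacementMaps:
    """Per-frame, per-pixel in-plane displacement vectors in micrometres."""

    ap: np.ndarray  # (frames, rows, cols), um
    cc: np.ndarray
    validity: np.ndarray  # (rows, cols) bool
    pixel_size: float  # mm
    frame_interval: float = DEFAULT_FRAME_INTERVAL  # ms

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.cc = np.asarray(self.cc, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.ap.shape != self.cc.shape or self.ap.ndim != 3:
            raise DenseError("ap and cc must share a 3D shape")
        if self.validity.shape != self.ap.shape[1:]:
            raise DenseError("validity mask must match the image plane")
        inside = self.validity
        if not (
            np.all(np.isfinite(self.ap[:, inside])) and np.all(np.isfinite(self.cc[:, inside]))
        ):
            raise DenseError("displacement values inside the validity mask must be finite")
        self.ap[:, ~inside] = 0.0
        self.cc[:, ~inside] = 0.0

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of (AP, CC) per frame and pixel, um."""
        return np.hypot(self.ap, self.cc)


@dataclass(frozen=True)
class DisplacementSummary:
    """Scalar displacement of one brain region from the circular-ROI rule."""

    region: str
    roi_center: tuple[int, int]
    roi_area: float  # mm^2 actually covered by the rasterized disc
    displacement: float  # um

    def __post_init__(self) -> None:
        if self.displacement < 0:
            raise DenseError("displacement must be non-negative")


# ---------------------------------------------------------------------------
# Operations


def unwrap_phase(series: DenseSeries, mask: RegionMask) -> DenseSeries:
    """Spatially unwrap each phase channel inside each region, per frame.

    A reliability-sorting 2D unwrapper runs within each region mask; pixels
    outside regions are left untouched.  A spatial unwrap fixes the field
    only up to a global 2 pi multiple per frame, so the multiple is anchored
    by temporal continuity: frame-to-frame mean phase change within a region
    is assumed below pi (satisfied at cine frame rates), and frame 0 is
    assumed unwrapped at the region median (early-cycle displacement is
    small).
    """
    out_ap = series.phase_ap.copy()
    out_cc = series.phase_cc.copy()
    for label in sorted(mask.names):
        region = mask.labels == label
        if region.sum() < 4:
            warnings.warn(
                f"region {mask.name_of(label)} has < 4 pixels; unwrap skipped",
                stacklevel=2,
            )
            continue
        for out in (out_ap, out_cc):
            prev = None
            for t in range(series.n_frames):
                frame = np.ma.array(out[t], mask=~region)
                unwrapped = np.asarray(_unwrap2d(frame))
                vals = unwrapped[region]
                if prev is None:
                    # anchor frame 0: bring the region median into (-pi, pi]
                    shift = 2 * np.pi * np.round(np.median(vals) / (2 * np.pi))
                else:
                    shift = 2 * np.pi * np.round(np.mean(vals - prev) / (2 * np.pi))
                out[t][region] = vals - shift
                prev = out[t][region]
    return replace(series, phase_ap=out_ap, phase_cc=out_cc, unwrapped=True)


def phase_to_displacement(series: DenseSeries, mask: RegionMask | None = None) -> DisplacementMaps:
    """Convert phase to displacement: ``u = phi / (2 pi k_e)``, in um.

    ``mask`` supplies the validity map (union of regions); without it every
    pixel is considered valid.
    """
    ke = series.encoding_frequency
    if ke <= 0:
        raise DenseError("encoding frequency must be positive")
    scale = 1000.0 / (2.0 * np.pi * ke)  # rad -> um (ke in cycles/mm)
    validity = (
        mask.labels > 0 if mask is not None else np.ones(series.magnitude.shape[1:], bool)
    )
    return DisplacementMaps(
        ap=series.phase_ap * scale,
        cc=series.phase_cc * scale,
        validity=validity,
        pixel_size=series.pixel_size,
        frame_interval=series.frame_interval,
    )


def _fir_kernel(cutoff: float, order: int) -> np.ndarray:
    if not 0 < cutoff < 1:
        raise DenseError("cutoff must lie in (0, 1)")
    if order <= 0 or order % 2:
        raise DenseError("filter order must be a positive even integer")
    return signal.firwin(order + 1, cutoff)  # Hamming-windowed sinc, unit DC gain


def filter_displacement(
    maps: DisplacementMaps,
    cutoff: float = DEFAULT_FIR_CUTOFF,
    order: int = DEFAULT_FIR_ORDER,
) -> DisplacementMaps:
    """Spatial low-pass noise filtering of the displacement maps.

    A 1D Hamming windowed-sinc FIR kernel (normalized cutoff ``cutoff``,
    ``order + 1`` taps) is applied separably along rows then columns of each
    frame, with replicated edges.  Filtering is restricted to the validity
    mask by normalized convolution (the map times the mask and the mask
    itself are filtered and divided), so zeros outside the regions do not
    bleed inwards.
    """
    kernel = _fir_kernel(cutoff, order)
    if min(maps.ap.shape[1:]) < kernel.size:
        raise DenseError(
            f"map plane {maps.ap.shape[1:]} smaller than the {kernel.size}-tap kernel"
        )

    def smooth2d(img: np.ndarray) -> np.ndarray:
        out = ndimage.convolve1d(img, kernel, axis=0, mode="nearest")
        return ndimage.convolve1d(out, kernel, axis=1, mode="nearest")

    w = maps.validity.astype(float)
    ws = smooth2d(w)
    ap = np.empty_like(maps.ap)
    cc = np.empty_like(maps.cc)
    with np.errstate(invalid="ignore", divide="ignore"):
        for t in range(maps.ap.shape[0]):
            ap[t] = np.where(maps.validity, smooth2d(maps.ap[t] * w) / ws, 0.0)
            cc[t] = np.where(maps.validity, smooth2d(maps.cc[t] * w) / ws, 0.0)
    return DisplacementMaps(
        ap=ap,
        cc=cc,
        validity=maps.validity,
        pixel_size=maps.pixel_size,
        frame_interval=maps.frame_interval,
    )


def erode_region(mask: RegionMask, width: int = DEFAULT_EROSION) -> RegionMask:
    """Erode each region inward by ``width`` voxels (boundary exclusion).

    Removes a band of voxels at each region boundary to avoid contaminating
    the displacement summary with partial-volume or non-brain structures.
    """
    if width < 0:
        raise DenseError("erosion width must be non-negative")
    if width == 0:
        return RegionMask(mask.labels.copy(), dict(mask.names), eroded=mask.eroded)
    labels = np.zeros_like(mask.labels)
    for label in sorted(mask.names):
        region = mask.labels == label
        if not region.any():
            continue
        eroded = ndimage.binary_erosion(region, iterations=width)
        if not eroded.any():
            raise DenseError(
                f"region {mask.name_of(label)} vanishes after {width}-voxel erosion"
            )
        labels[eroded] = label
    return RegionMask(labels, dict(mask.names), eroded=True)


def _disc_offsets(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius_px**2
    return dy[keep], dx[keep]


def summarize_region(
    maps: DisplacementMaps,
    mask: RegionMask,
    region: int | str,
    roi_area: float = DEFAULT_ROI_AREA,
    statistic: str = "mean",
) -> DisplacementSummary:
    """Peak displacement of a region via the circular-ROI rule.

    Each pixel's temporal peak displacement magnitude is computed; a disc of
    area ``roi_area`` mm^2 is centred on the largest-peak pixel (shifted
    minimally if the disc would leave the region), and the region's reported
    displacement is the temporal maximum of the disc's spatial-mean magnitude
    (``statistic="mean"``, the default) or of its spatial maximum
    (``statistic="max"``).
    """
    if statistic not in ("mean", "max"):
        raise DenseError("statistic must be 'mean' or 'max'")
    region_mask = mask.region(region)
    name = mask.name_of(mask.label_of(region))
    if not region_mask.any():
        raise DenseError(f"region {name} is empty")
    mag = maps.magnitude()
    peak = mag.max(axis=0)  # temporal peak per pixel
    radius_px = np.sqrt(roi_area / np.pi) / maps.pixel_size
    dy, dx = _disc_offsets(radius_px)

    # centres whose disc stays inside the region
    disc = np.zeros((2 * int(np.ceil(radius_px)) + 1,) * 2, dtype=bool)
    disc[dy + int(np.ceil(radius_px)), dx + int(np.ceil(radius_px))] = True
    feasible = ndimage.binary_erosion(region_mask, structure=disc)
    if not feasible.any():
        raise DenseError(
            f"a {roi_area} mm^2 ROI does not fit inside region {name}"
        )

    peak_in = np.where(region_mask, peak, -np.inf)
    argmax = np.unravel_index(np.argmax(peak_in), peak.shape)
    if feasible[argmax]:
        center = argmax
    else:  # shift minimally to the nearest feasible centre
        fy, fx = np.nonzero(feasible)
        k = np.argmin((fy - argmax[0]) ** 2 + (fx - argmax[1]) ** 2)
        center = (int(fy[k]), int(fx[k]))

    rows = center[0] + dy
    cols = center[1] + dx
    roi_series = mag[:, rows, cols]
    value = roi_series.mean(axis=1).max() if statistic == "mean" else roi_series.max()
    return DisplacementSummary(
        region=name,
        roi_center=(int(center[0]), int(center[1])),
        roi_area=float(dy.size) * maps.pixel_size**2,
        displacement=float(value),
    )


def measure_displacement(
    series: DenseSeries,
    mask: RegionMask,
    erosion: int = DEFAULT_EROSION,
    cutoff: float = DEFAULT_FIR_CUTOFF,
    order: int = DEFAULT_FIR_ORDER,
    roi_area: float = DEFAULT_ROI_AREA,
    statistic: str = "mean",
) -> dict[str, DisplacementSummary]:
    """Full measurement chain: unwrap, decode, filter, erode, summarize.

    Noise filtering runs within each segmented region separately (the
    normalized convolution is restricted to that region's support), so
    neighbouring regions with different motion do not blend across the
    segmentation boundary.  Returns one :class:`DisplacementSummary` per
    named region.
    """
    unwrapped = series if series.unwrapped else unwrap_phase(series, mask)
    maps = phase_to_displacement(unwrapped, mask)
    eroded = mask if mask.eroded else erode_region(mask, erosion)
    out: dict[str, DisplacementSummary] = {}
    for label, name in mask.names.items():
        region = mask.labels == label
        if not region.any() or not (eroded.labels == label).any():
            continue
        region_maps = DisplacementMaps(
            ap=maps.ap.copy(),
            cc=maps.cc.copy(),
            validity=region,
            pixel_size=maps.pixel_size,
            frame_interval=maps.frame_interval,
        )
        filtered = filter_displacement(region_maps, cutoff=cutoff, order=order)
        out[name] = summarize_region(
            filtered, eroded, name, roi_area=roi_area, statistic=statistic
        )
    return out


# ---------------------------------------------------------------------------
# I/O (NIfTI series + JSON sidecar)


def save_series(series: DenseSeries, directory) -> None:
    """Write magnitude/phase channels as 4D NIfTI plus a JSON sidecar."""
    import json
    from pathlib import Path

    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag([series.pixel_size, series.pixel_size, 1.0, 1.0])
    for name in ("magnitude", "phase_ap", "phase_cc"):
        arr = np.moveaxis(getattr(series, name), 0, -1)[:, :, None, :]
        nib.save(nib.Nifti1Image(arr, affine), str(directory / f"{name}.nii"))
    sidecar = {
        "ke_cycles_per_mm": series.encoding_frequency,
        "frame_interval_ms": series.frame_interval,
        "pixel_size_mm": series.pixel_size,
        "unwrapped": series.unwrapped,
    }
    (directory / "series.json").write_text(json.dumps(sidecar, indent=2))


def load_series(directory) -> DenseSeries:
    """Read a series written by :func:`save_series`."""
    import json
    from pathlib import Path

    import nibabel as nib

    directory = Path(directory)
    sidecar = json.loads((directory / "series.json").read_text())
    arrays = {}
    for name in ("magnitude", "phase_ap", "phase_cc"):
        path = directory / f"{name}.nii"
        if not path.exists():
            raise DenseError(f"missing DENSE channel file: {path}")
        arrays[name] = np.moveaxis(np.asanyarray(nib.load(str(path)).dataobj)[:, :, 0, :], -1, 0)
    return DenseSeries(
        pixel_size=sidecar["pixel_size_mm"],
        frame_interval=sidecar["frame_interval_ms"],
        encoding_frequency=sidecar["ke_cycles_per_mm"],
        unwrapped=sidecar.get("unwrapped", False),
        **arrays,
    )


def save_region_mask(mask: RegionMask, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), np.eye(4)), str(path))


def load_region_mask(path, names=None) -> RegionMask:
    import nibabel as nib

    labels = np.asanyarray(nib.load(str(path)).dataobj).astype(int)
    kw = {"names": names} if names else {}
    return RegionMask(labels, **kw)
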