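import numpy as np
import pytest

from csfm.geometry import CrossSection


def rasterize_disc(radius_cm: float, spacing_cm: float, center=(0.0, 0.0)) -> np.ndarray:
    """Boolean raster of a disc, pixel centres inside the radius."""
    half = radius_cm + 3 * spacing_cm
    n = 2 * int(np.ceil(half / spacing_cm)) + 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    x = (xx - c) * spacing_cm - center[0]
    y = (yy - c) * spacing_cm - center[1]
    return x**2 + y**2 < radius_cm**2


def rasterize_annulus(
    r_inner: float, r_outer: float, spacing_cm: float, offset: float = 0.0
) -> np.ndarray:
    """Boolean raster of an annulus; inner circle centre offset along x."""
    half = r_outer + 3 * spacing_cm
    n = 2 * int(np.ceil(half / spacing_cm)) + 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    x = (xx - c) * spacing_cm
    y = (yy - c) * spacing_cm
    r_out = np.hypot(x, y)
    r_in = np.hypot(x - offset, y)
    return (r_out < r_outer) & (r_in > r_inner)


def section_from_mask(mask: np.ndarray, spacing_cm: float, z: float = 0.0) -> CrossSection:
    return CrossSection(mask, pixel_spacing=spacing_cm * 10.0, z=z)


@pytest.fixture
def disc_section():
    """Unit-radius disc at 0.02 cm/pixel."""
    return section_from_mask(rasterize_disc(1.0, 0.02), 0.02)


@pytest.fixture
def annulus_section():
    """Concentric annulus Ri=0.5, Ro=0.8 cm at 0.01 cm/pixel."""
    return section_from_mask(rasterize_annulus(0.5, 0.8, 0.01), 0.01)
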