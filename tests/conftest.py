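import numpy as np
import pytest

from osteolam.xgeom import SectionImage


def render_mask(predicate, extent_mm: float, pitch: float) -> np.ndarray:
    """Rasterize ``predicate(x, y)`` (mm, y up, origin center) on a square grid."""
    half = int(np.ceil(extent_mm / pitch)) + 2
    n = 2 * half + 1
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    x = (cols - half) * pitch
    y = -(rows - half) * pitch
    return predicate(x, y)


def make_disc(radius_mm: float = 1.0, pitch: float = 1e-3) -> SectionImage:
    mask = render_mask(lambda x, y: x * x + y * y <= radius_mm ** 2,
                       radius_mm * 1.05, pitch)
    return SectionImage(raster=mask.astype(np.uint8), pixel_pitch=pitch)


def make_annulus(ro: float = 1.0, ri: float = 0.5,
                 pitch: float = 1e-3) -> SectionImage:
    def pred(x, y):
        r2 = x * x + y * y
        return (r2 <= ro ** 2) & (r2 >= ri ** 2)

    return SectionImage(raster=render_mask(pred, ro * 1.05, pitch).astype(np.uint8),
                        pixel_pitch=pitch)


def render_ellipse_pixels(a_px: float, b_px: float, angle_deg: float = 0.0,
                          center=(0.0, 0.0)) -> np.ndarray:
    """(row, col) pixel coordinates inside an ellipse with semi-axes in px."""
    extent = int(np.ceil(max(a_px, b_px))) + 2
    cols, rows = np.meshgrid(np.arange(-extent, extent + 1),
                             np.arange(-extent, extent + 1))
    phi = np.radians(angle_deg)
    # angle measured from the horizontal (column) axis, y up
    u = cols * np.cos(phi) + (-rows) * np.sin(phi)
    v = -cols * np.sin(phi) + (-rows) * np.cos(phi)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    rr, cc = np.nonzero(inside)
    return np.column_stack([rr + center[0], cc + center[1]])


@pytest.fixture(scope="session")
def annulus_section() -> SectionImage:
    return make_annulus(ro=1.0, ri=0.5, pitch=1e-3)
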