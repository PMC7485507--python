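"""Vascular-canal orientation scoring and the laminarity index.

The laminarity index (LI) of a bone section is the number of circumferential
primary vascular canals divided by the total number of primary canals.  A
canal's three-dimensional orientation is inferred from its transverse profile:
a cylindrical canal tilted by ``theta`` from the section normal cuts the
section plane in an ellipse of aspect ratio ``1/cos(theta)``, so

* aspect ratio < 3            -> longitudinal;
* otherwise the angle between the ellipse major axis and the local periosteal
  tangent decides: [0, 22.5) deg -> circumferential, [22.5, 67.5) deg ->
  oblique, [67.5, 90] deg -> radial.

Because the periosteal tangent varies around a curved cortex, each of the four
cardinal anatomical octants is first *straightened*: the cortex band is
resampled so the periosteal surface becomes the horizontal top edge and local
angles are preserved.  Canal profiles are then segmented (branched canals are
split at skeleton nodes), fitted with moment-matched ellipses and classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .xgeom import (
    PRIMARY_CANAL,
    POROSITY_LIMIT,
    SectionImage,
    _periosteal_contour,
    compute_porosity,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("longitudinal", "circumferential", "radial", "oblique")

#: aspect-ratio threshold separating longitudinal from transverse profiles
AR_THRESHOLD = 3.0
#: half-width of the circumferential / radial angle bins, degrees
ANGLE_BIN = 22.5
#: smallest component (px) for which a moment ellipse is considered stable
MIN_COMPONENT_PX = 8

CARDINAL_DIRECTIONS = {
    "forelimb": ("cranial", "caudal", "dorsal", "ventral"),
    "hindlimb": ("cranial", "caudal", "medial", "lateral"),
}

_DIRECTION_ANGLE = {"right": 0.0, "up": 90.0, "left": 180.0, "down": 270.0}


# ---------------------------------------------------------------------------
# orientation trigonometry and the four-way classification rule
# ---------------------------------------------------------------------------

def ar_to_angle(aspect_ratio: float) -> float:
    """Tilt from the longitudinal (section-normal) axis implied by a profile
    aspect ratio, in degrees: ``(180/pi) * acos(1/AR)``.

    An aspect ratio of 1 is a canal running perpendicular to the section
    (0 deg); the transverse threshold AR = 3 corresponds to 70.5 deg.
    """
    ar = float(aspect_ratio)
    if ar < 1.0:
        raise ValueError("aspect ratio must be >= 1")
    return float(np.degrees(np.arccos(1.0 / ar)))


def angle_to_ar(angle_deg: float) -> float:
    """Inverse of :func:`ar_to_angle`: aspect ratio ``1/cos(angle)`` of the
    profile of a cylinder tilted ``angle_deg`` from the section normal."""
    a = float(angle_deg)
    if not 0.0 <= a < 90.0:
        raise ValueError("tilt must be in [0, 90) degrees")
    return float(1.0 / np.cos(np.radians(a)))


def classify_canal(aspect_ratio: float, angle: float) -> str:
    """Assign one of the four orientation categories.

    ``angle`` is measured between the profile's major axis and the periosteal
    tangent (horizontal in straightened coordinates), folded into [0, 90].
    Bins are half-open so the partition is exact; AR exactly 3 counts as
    transverse.
    """
    if aspect_ratio < 1.0:
        raise ValueError("aspect ratio must be >= 1")
    if not 0.0 <= angle <= 90.0:
        raise ValueError("angle must be in [0, 90] degrees")
    if aspect_ratio < AR_THRESHOLD:
        return "longitudinal"
    if angle < ANGLE_BIN:
        return "circumferential"
    if angle < 90.0 - ANGLE_BIN:
        return "oblique"
    return "radial"


# ---------------------------------------------------------------------------
# moment-based ellipse fit
# ---------------------------------------------------------------------------

_DEGENERATE_AR_CAP = 1e6


def fit_ellipse(pixels: np.ndarray) -> tuple[float, float, float]:
    """Moment-matched ellipse of a pixel component.

    Parameters
    ----------
    pixels
        (N, 2) array of (row, col) pixel coordinates.

    Returns
    -------
    (major, minor, angle)
        Full axis lengths in px of the uniform ellipse with the same area and
        second moments (each pixel contributes its own 1/12 square moment),
        and the angle in degrees between the major axis and the horizontal
        (column) axis, folded into [0, 90].
    """
    pts = np.asarray(pixels, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("pixels must be an (N, 2) array of (row, col)")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = evals
    v_major = evecs[:, 1]  # (d_row, d_col)

    major = 4.0 * np.sqrt(max(lam_major, 0.0))
    minor = 4.0 * np.sqrt(max(lam_minor, 0.0))

    angle = np.degrees(np.arctan2(abs(v_major[0]), abs(v_major[1])))
    if minor <= 0.0 or major / minor > _DEGENERATE_AR_CAP:
        minor = major / _DEGENERATE_AR_CAP
    return float(major), float(minor), float(angle)


# ---------------------------------------------------------------------------
# octant extraction and cortex straightening
# ---------------------------------------------------------------------------

@dataclass
class OctantImage:
    """A straightened 45-degree cortical sector.

    Rows run from the periosteal surface (row 0) inward; columns run along
    periosteal arc length.  ``src_rows``/``src_cols`` map each straightened
    pixel back to (fractional) source raster coordinates, so features can be
    traced to section coordinates.  The raster may include an angular margin
    beyond the nominal sector (see ``half_span``/``pad``): membership tests
    use original-coordinate polar angles, not raster bounds.
    """

    raster: np.ndarray
    octant_label: str
    arc_origin: float            # sector center angle, deg, image frame (y up)
    half_span: float             # nominal sector half width, deg
    pad: float                   # extra angular margin straightened, deg
    src_rows: np.ndarray
    src_cols: np.ndarray
    centroid_rc: tuple[float, float]   # section centroid (row, col) px
    pixel_pitch: float

    def polar_angle_of(self, row: float, col: float) -> float:
        """Polar angle (deg, in [0, 360), y-up convention) of a source-raster
        point about the section centroid."""
        r0, c0 = self.centroid_rc
        return float(np.degrees(np.arctan2(-(row - r0), col - c0)) % 360.0)

    def in_sector(self, row: float, col: float) -> bool:
        theta = self.polar_angle_of(row, col)
        d = (theta - self.arc_origin + 180.0) % 360.0 - 180.0
        return -self.half_span <= d < self.half_span


def _resample_arc(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    seg = np.diff(points, axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    total = s[-1]
    n = max(int(np.floor(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])])


def straighten_octant(
    section: SectionImage,
    center_angle: float,
    octant_label: str = "",
    half_span: float = 22.5,
    pad: float = 6.0,
    smooth_sigma: float = 5.0,
) -> OctantImage:
    """Resample a cortical sector into a band with a horizontal periosteal edge.

    The periosteal outer contour is parameterized by arc length over the
    sector ``[center_angle - half_span - pad, center_angle + half_span + pad]``
    and source pixels are sampled along inward normals.  Depth steps are
    curvature-corrected per column, ``d(j) = (1 - exp(-kappa*j)) / kappa``,
    which makes the mapping locally conformal (the exact log-polar unwrap when
    the contour is circular), so local angles relative to the periosteal
    tangent and profile aspect ratios are preserved at every depth — not only
    near the surface.  Labels are resampled per-label with bilinear
    interpolation and a 0.5 threshold.
    """
    raster = section.raster
    contour = _periosteal_contour(section)  # (row, col), closed
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]

    rows_b, cols_b = np.nonzero(raster > 0)
    if rows_b.size == 0:
        raise ValueError("empty section")
    r0 = float(rows_b.mean())
    c0 = float(cols_b.mean())

    # smooth the *closed* contour (wrap mode) so tangents and curvature are
    # free of marching-squares jaggies and of end effects at the sector edges
    contour = _resample_arc(np.vstack([contour, contour[:1]]), spacing=1.0)[:-1]
    if smooth_sigma > 0 and len(contour) > 8:
        contour = np.column_stack([
            ndimage.gaussian_filter1d(contour[:, 0], smooth_sigma, mode="wrap"),
            ndimage.gaussian_filter1d(contour[:, 1], smooth_sigma, mode="wrap"),
        ])

    tangent = np.gradient(contour, axis=0)
    tnorm = np.hypot(tangent[:, 0], tangent[:, 1])
    tangent /= np.maximum(tnorm, 1e-12)[:, None]
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    to_center = np.array([r0, c0]) - contour
    flip = np.sum(normal * to_center, axis=1) < 0
    normal[flip] *= -1.0

    # signed curvature of the inward-normal field: n'(s) = -kappa * t(s).
    # the depth schedule below is very sensitive to kappa noise (depth error
    # ~ j^2/2 * dkappa), so kappa gets much heavier smoothing than the path
    dn = np.gradient(normal, axis=0)
    kappa = -np.sum(dn * tangent, axis=1)
    kappa_sigma = max(4.0 * smooth_sigma, 20.0)
    if len(kappa) > 8:
        kappa = ndimage.gaussian_filter1d(kappa, kappa_sigma, mode="wrap")

    theta = np.degrees(np.arctan2(-(contour[:, 0] - r0), contour[:, 1] - c0)) % 360.0
    d = (theta - center_angle + 180.0) % 360.0 - 180.0
    span = half_span + pad
    mask = np.abs(d) <= span
    if not mask.any():
        raise ValueError(f"no periosteal arc found in sector at {center_angle} deg")

    # longest circular run of in-sector contour points
    m2 = np.concatenate([mask, mask])
    best_start = best_len = cur_start = cur_len = 0
    for i, flag in enumerate(m2):
        if flag:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    best_len = min(best_len, len(mask))
    idx = (best_start + np.arange(best_len)) % len(mask)

    # orient the arc so columns run with increasing angular offset
    d_arc = (theta[idx] - center_angle + 180.0) % 360.0 - 180.0
    if d_arc[0] > d_arc[-1]:
        idx = idx[::-1]
    arc = contour[idx]
    normal = normal[idx]
    kappa = kappa[idx]

    # maximum cortical depth from the periosteal surface
    envelope = section.cortical_envelope()
    depth_map = ndimage.distance_transform_edt(envelope)
    t_max = float(depth_map[raster > 0].max()) + 2.0

    # conformal depth schedule per column; saturates at the focal distance 1/kappa
    def depth(j: np.ndarray, k: float) -> np.ndarray:
        if abs(k) < 1e-9:
            return j.astype(float)
        return (1.0 - np.exp(-k * j)) / k

    # number of rows: enough for every column to reach t_max (or its cap)
    n_rows = 0
    for k in (float(kappa.min()), float(kappa.max())):
        if k > 1e-9:
            reach = min(t_max, 0.95 / k)
            n_rows = max(n_rows, int(np.ceil(-np.log(1.0 - k * reach) / k)) + 1)
        else:
            n_rows = max(n_rows, int(np.ceil(t_max)) + 1)
    n_rows = min(n_rows, int(6 * t_max) + 2)

    j = np.arange(n_rows, dtype=float)
    n_cols = len(arc)
    depths = np.empty((n_rows, n_cols))
    for i in range(n_cols):
        k = kappa[i]
        if k > 1e-9:
            cap = 0.95 / k
            depths[:, i] = np.minimum(depth(j, k), cap)
        else:
            depths[:, i] = depth(j, k)

    src_rows = arc[:, 0][None, :] + depths * normal[:, 0][None, :]
    src_cols = arc[:, 1][None, :] + depths * normal[:, 1][None, :]

    out = np.zeros((n_rows, n_cols), dtype=np.uint8)
    best = np.zeros((n_rows, n_cols))
    coords = np.array([src_rows.ravel(), src_cols.ravel()])
    for label in (1, 2, 3, 4):
        indicator = (raster == label).astype(float)
        vals = ndimage.map_coordinates(indicator, coords, order=1, cval=0.0)
        vals = vals.reshape(n_rows, n_cols)
        take = (vals >= 0.5) & (vals > best)
        out[take] = label
        best = np.maximum(best, vals)

    return OctantImage(
        raster=out,
        octant_label=octant_label,
        arc_origin=center_angle,
        half_span=half_span,
        pad=pad,
        src_rows=src_rows,
        src_cols=src_cols,
        centroid_rc=(r0, c0),
        pixel_pitch=section.pixel_pitch,
    )


def cardinal_angles(section: SectionImage) -> dict[str, float]:
    """Image-frame polar angle (deg, y-up) of each cardinal anatomical
    direction, from the section's orientation map."""
    inverse = {v: _DIRECTION_ANGLE[k] for k, v in section.orientation_map.items()}
    try:
        names = CARDINAL_DIRECTIONS[section.limb]
    except KeyError:
        raise ValueError(f"unknown limb type {section.limb!r}") from None
    missing = [n for n in names if n not in inverse]
    if missing:
        raise ValueError(f"orientation map lacks cardinal directions: {missing}")
    return {name: inverse[name] for name in names}


def extract_cardinal_octants(
    section: SectionImage,
    pad: float = 6.0,
    enforce_porosity_gate: bool = True,
) -> dict[str, OctantImage]:
    """Straighten the four cardinal 45-degree octants of a section.

    Each octant is the sector ``[center - 22.5, center + 22.5)`` about the
    section centroid, centered on a cardinal anatomical direction (cranial,
    caudal and dorsal/ventral or medial/lateral depending on the limb).
    Sections above the porosity limit are rejected: cancellous bone violates
    the cylindrical-canal assumption behind the ellipse-fit classification.
    """
    if enforce_porosity_gate:
        porosity, excluded = compute_porosity(section)
        if excluded:
            raise ValueError(
                f"porosity {porosity:.3f} exceeds {POROSITY_LIMIT}: "
                "section is cancellous; laminarity is not scored"
            )
    return {
        name: straighten_octant(section, angle, octant_label=name, pad=pad)
        for name, angle in cardinal_angles(section).items()
    }


# ---------------------------------------------------------------------------
# canal segmentation
# ---------------------------------------------------------------------------

@dataclass
class CanalProfile:
    """One in-plane primary-canal profile with its fitted ellipse."""

    component_id: int
    pixel_count: int
    centroid: tuple[float, float]        # straightened (row, col)
    source_centroid: tuple[float, float]  # original raster (row, col)
    ellipse_major: float                 # px, full axis
    ellipse_minor: float                 # px, full axis
    aspect_ratio: float
    angle: float                         # deg to periosteal tangent, [0, 90]
    category: str
    octant_label: str
    kind: str = "primary"


def _split_at_branches(component_mask: np.ndarray) -> np.ndarray:
    """Label sub-components of a branched canal, split at skeleton nodes.

    Returns an int image (same shape, 0 = not in component).  Components whose
    skeleton has no branch point come back as a single label.  Pixels are
    assigned to the nearest skeleton branch segment.
    """
    skel = morphology.skeletonize(component_mask)
    if not skel.any():
        lab = np.zeros(component_mask.shape, dtype=int)
        lab[component_mask] = 1
        return lab
    neighbors = ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                                 mode="constant") - 1
    branch_points = skel & (neighbors > 2)
    if not branch_points.any():
        lab = np.zeros(component_mask.shape, dtype=int)
        lab[component_mask] = 1
        return lab
    segments = skel & ~branch_points
    seg_labels, n_seg = ndimage.label(segments, structure=np.ones((3, 3), int))
    if n_seg <= 1:
        lab = np.zeros(component_mask.shape, dtype=int)
        lab[component_mask] = 1
        return lab
    # skeletons of clean elliptical blobs sprout short spurs at their ends;
    # only segments that are a substantial share of the skeleton count as
    # genuine branches worth splitting at
    sizes = ndimage.sum_labels(np.ones(seg_labels.shape), seg_labels,
                               np.arange(1, n_seg + 1))
    threshold = max(5.0, 0.2 * float(skel.sum()))
    significant = np.flatnonzero(sizes >= threshold) + 1
    if len(significant) < 2:
        lab = np.zeros(component_mask.shape, dtype=int)
        lab[component_mask] = 1
        return lab
    keep_mask = np.isin(seg_labels, significant)
    seg_rc = np.column_stack(np.nonzero(keep_mask))
    seg_ids = seg_labels[keep_mask]
    tree = cKDTree(seg_rc)
    comp_rc = np.column_stack(np.nonzero(component_mask))
    _, nearest = tree.query(comp_rc)
    out = np.zeros(component_mask.shape, dtype=int)
    out[comp_rc[:, 0], comp_rc[:, 1]] = seg_ids[nearest]
    return out


def segment_canal_profiles(octant: OctantImage,
                           min_pixels: int = MIN_COMPONENT_PX) -> list[CanalProfile]:
    """Extract primary-canal profiles from a straightened octant.

    Connected components of primary-canal pixels; branched components are
    divided at skeleton branch nodes.  Secondary (Haversian) canals are
    excluded, as is traditional for laminarity counts.  Components below
    ``min_pixels`` are dropped and logged: their moment ellipses are
    unresolvable.
    """
    mask = octant.raster == PRIMARY_CANAL
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    profiles: list[CanalProfile] = []
    next_id = 0
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        if comp_mask.sum() < min_pixels:
            logger.debug("dropping %d px component (< %d px)",
                         int(comp_mask.sum()), min_pixels)
            continue
        for sub in np.unique(sub_labels := _split_at_branches(comp_mask)):
            if sub == 0:
                continue
            pts = np.column_stack(np.nonzero(sub_labels == sub))
            if len(pts) < min_pixels:
                logger.debug("dropping %d px branch segment", len(pts))
                continue
            major, minor, angle = fit_ellipse(pts)
            ar = major / minor if minor > 0 else _DEGENERATE_AR_CAP
            rr = pts[:, 0].astype(int)
            cc = pts[:, 1].astype(int)
            src_r = float(np.mean(octant.src_rows[rr, cc]))
            src_c = float(np.mean(octant.src_cols[rr, cc]))
            profiles.append(CanalProfile(
                component_id=next_id,
                pixel_count=len(pts),
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                source_centroid=(src_r, src_c),
                ellipse_major=major,
                ellipse_minor=minor,
                aspect_ratio=ar,
                angle=angle,
                category=classify_canal(ar, angle),
                octant_label=octant.octant_label,
            ))
            next_id += 1
    return profiles


# ---------------------------------------------------------------------------
# laminarity index
# ---------------------------------------------------------------------------

@dataclass
class LaminarityResult:
    """Per-octant orientation counts and the pooled laminarity index."""

    octant_counts: Mapping[str, Mapping[str, int]]
    octant_li: Mapping[str, float]
    pooled_li: float
    mean_octant_li: float
    total_canals: int
    sampled_fraction: float | None = None


def compute_laminarity(
    profiles: Iterable[CanalProfile],
    octant_labels: Sequence[str] | None = None,
    total_primary_canals: int | None = None,
) -> LaminarityResult:
    """Count categories per octant and form the laminarity index.

    The headline LI pools circumferential and total counts over the four
    cardinal octants before dividing (canal-weighted); the unweighted mean of
    per-octant LIs is also reported for comparison.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no classified canal profiles")
    if octant_labels is None:
        octant_labels = sorted({p.octant_label for p in profiles})
    counts: dict[str, dict[str, int]] = {
        oc: {cat: 0 for cat in CATEGORIES} for oc in octant_labels
    }
    for p in profiles:
        counts.setdefault(p.octant_label, {cat: 0 for cat in CATEGORIES})
        counts[p.octant_label][p.category] += 1

    octant_li = {}
    for oc, c in counts.items():
        total = sum(c.values())
        octant_li[oc] = c["circumferential"] / total if total else float("nan")

    total = sum(sum(c.values()) for c in counts.values())
    circ = sum(c["circumferential"] for c in counts.values())
    pooled = circ / total
    with_canals = [li for li in octant_li.values() if not np.isnan(li)]
    mean_li = float(np.mean(with_canals)) if with_canals else float("nan")
    frac = total / total_primary_canals if total_primary_canals else None
    return LaminarityResult(
        octant_counts=counts,
        octant_li=octant_li,
        pooled_li=pooled,
        mean_octant_li=mean_li,
        total_canals=total,
        sampled_fraction=frac,
    )


def count_primary_canals(section: SectionImage,
                         min_pixels: int = MIN_COMPONENT_PX) -> int:
    """Number of primary-canal connected components in the full section."""
    labels, n = ndimage.label(section.raster == PRIMARY_CANAL,
                              structure=np.ones((3, 3), int))
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return int(np.sum(sizes >= min_pixels))


def score_section(
    section: SectionImage,
    pad: float = 6.0,
    min_pixels: int = MIN_COMPONENT_PX,
    enforce_porosity_gate: bool = True,
) -> tuple[LaminarityResult, list[CanalProfile]]:
    """Full laminarity pipeline for one section.

    Extracts and straightens the four cardinal octants, segments and
    classifies primary-canal profiles, and pools them into an LI.  Profiles
    are retained only if their centroid's polar angle (original coordinates)
    falls inside the nominal 45-degree sector, so canals straddling the
    straightened margin are neither clipped nor double-counted.
    """
    octants = extract_cardinal_octants(section, pad=pad,
                                       enforce_porosity_gate=enforce_porosity_gate)
    kept: list[CanalProfile] = []
    for octant in octants.values():
        for p in segment_canal_profiles(octant, min_pixels=min_pixels):
            if octant.in_sector(*p.source_centroid):
                kept.append(p)
    result = compute_laminarity(
        kept,
        octant_labels=list(octants),
        total_primary_canals=count_primary_canals(section, min_pixels) or None,
    )
    return result, kept
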