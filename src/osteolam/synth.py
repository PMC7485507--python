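"""Synthetic bone sections and ontogenetic series with analytic ground truth.

Sections are annular cortices with cylindrical vascular canals.  A canal
tilted by ``tilt`` degrees from the section normal cuts the section plane in
an ellipse with semi-axes ``(canal_radius, canal_radius / cos(tilt))``; its
major axis makes the canal's ``azimuth`` angle with the local periosteal
tangent.  Each canal's true orientation category is computed from
``(tilt, azimuth)`` through the *same* classification rule the measurement
pipeline applies to fitted ellipses, so section generation and laminarity
scoring can be round-trip tested against each other.

Ontogenetic series follow a power law on the torsional proxy,
``log10 Zp = b + a*log10 M`` with optional lognormal noise, and a laminarity
index drawn from a beta distribution whose mean declines logit-linearly along
the first principal component of the robustly standardized (mass, length, Zp)
triple — the same data model the inference chain assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from . import ontostats
from .canals import angle_to_ar, classify_canal
from .xgeom import SectionImage

_KIND_LABEL = {"primary": 2, "secondary": 3}
MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class CanalTruth:
    """Ground truth for one cylindrical canal crossing the section plane.

    ``radial_position``/``polar_angle`` may be None, in which case
    :func:`generate_section` places the canal by rejection sampling.
    """

    tilt: float                       # deg from the longitudinal axis, [0, 90)
    azimuth: float                    # deg of the in-plane projection to the
                                      # local periosteal tangent, [0, 90]
    canal_radius: float               # mm
    kind: str = "primary"
    radial_position: float | None = None   # mm from section centroid
    polar_angle: float | None = None       # deg, section-plane position

    def __post_init__(self):
        if not 0.0 <= self.tilt < 90.0:
            raise ValueError("tilt must be in [0, 90)")
        if not 0.0 <= self.azimuth <= 90.0:
            raise ValueError("azimuth must be in [0, 90]")
        if self.canal_radius <= 0:
            raise ValueError("canal_radius must be positive")
        if self.kind not in _KIND_LABEL:
            raise ValueError("kind must be 'primary' or 'secondary'")

    @property
    def aspect_ratio(self) -> float:
        """Profile aspect ratio of the tilted cylinder: 1/cos(tilt)."""
        return angle_to_ar(self.tilt)

    @property
    def true_category(self) -> str:
        """Orientation category under the shared classification rule."""
        return classify_canal(self.aspect_ratio, self.azimuth)


@dataclass
class SyntheticSectionSpec:
    """Annular cortex with a list of canals to render.

    ``cortex_noise`` roughens the periosteal and endosteal boundaries with a
    smooth angular perturbation of the given amplitude (px); 0 gives exact
    circles.  Canal density and radii are deliberately caller-chosen — there
    is no universal "realistic" value; see the methods note.
    """

    outer_radius: float               # mm
    inner_radius: float               # mm
    pixel_pitch: float                # mm/px
    canal_list: Sequence[CanalTruth] = field(default_factory=tuple)
    rng_seed: int = 0
    cortex_noise: float = 0.0         # boundary roughness amplitude, px

    def __post_init__(self):
        if not 0.0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.cortex_noise < 0:
            raise ValueError("cortex_noise must be >= 0")


def random_canals(n: int, rng: np.random.Generator,
                  canal_radius: float = 0.02,
                  tilt_range: tuple[float, float] = (0.0, 80.0),
                  azimuth_range: tuple[float, float] = (0.0, 90.0),
                  kind: str = "primary") -> list[CanalTruth]:
    """Draw ``n`` unplaced canals with uniform tilt and azimuth."""
    return [
        CanalTruth(
            tilt=float(rng.uniform(*tilt_range)),
            azimuth=float(rng.uniform(*azimuth_range)),
            canal_radius=canal_radius,
            kind=kind,
        )
        for _ in range(n)
    ]


def _boundary_perturbation(rng: np.random.Generator, amplitude_px: float,
                           n_harmonics: int = 6):
    """Smooth 2*pi-periodic radial perturbation r(theta), amplitude in px."""
    if amplitude_px == 0:
        return lambda theta: np.zeros_like(theta)
    orders = np.arange(2, 2 + n_harmonics)
    amps = rng.normal(size=n_harmonics) / orders
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    amps *= amplitude_px / max(np.sum(np.abs(amps)), 1e-12)

    def f(theta):
        return sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, orders, phases))

    return f


def generate_section(spec: SyntheticSectionSpec) -> tuple[SectionImage, pd.DataFrame]:
    """Render a labelled section raster and its ground-truth canal table.

    Canals without explicit positions are placed by rejection sampling inside
    the cortex with a clearance margin; overlapping placements are resampled
    up to ``MAX_PLACEMENT_ATTEMPTS`` times before the spec is declared
    over-dense.  Each canal is rasterized as the exact analytic ellipse a
    tilted cylinder cuts on the section plane, by pixel-center inclusion.
    Labels: 0 background, 1 bone, 2 primary canal, 3 secondary canal.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ro, ri, pitch = spec.outer_radius, spec.inner_radius, spec.pixel_pitch

    half = int(np.ceil(ro * 1.05 / pitch)) + 2
    n_px = 2 * half + 1
    c = half
    cols, rows = np.meshgrid(np.arange(n_px), np.arange(n_px))
    x = (cols - c) * pitch
    y = -(rows - c) * pitch          # y up so polar angles are conventional
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)

    perturb = _boundary_perturbation(rng, spec.cortex_noise)
    r_out = ro + perturb(theta) * pitch
    r_in = ri + perturb(theta + 1.7) * pitch
    raster = np.zeros((n_px, n_px), dtype=np.uint8)
    raster[(rho <= r_out) & (rho >= r_in)] = 1

    # place canals: centers must keep the whole ellipse inside the cortex
    margin = 2.0 * pitch
    placed: list[CanalTruth] = []
    for canal in spec.canal_list:
        a = canal.canal_radius * canal.aspect_ratio  # semi-major, mm
        lo = ri + a + margin
        hi = ro - a - margin
        if hi <= lo:
            raise ValueError("canal too large for the cortical band")
        if canal.radial_position is not None and canal.polar_angle is not None:
            if not lo <= canal.radial_position <= hi:
                raise ValueError("explicit canal position leaves the cortex")
            placed.append(canal)
            continue
        ok = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            rp = float(rng.uniform(lo, hi))
            pa = float(rng.uniform(0.0, 360.0))
            cand = replace(canal, radial_position=rp, polar_angle=pa)
            if _clear_of(cand, placed, margin):
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place canal after {MAX_PLACEMENT_ATTEMPTS} attempts: "
                "spec is over-dense for non-overlapping cylindrical canals"
            )

    records = []
    for canal in placed:
        pa = np.radians(canal.polar_angle)
        cx_mm = canal.radial_position * np.cos(pa)
        cy_mm = canal.radial_position * np.sin(pa)
        a = canal.canal_radius * canal.aspect_ratio
        b = canal.canal_radius
        # local periosteal tangent direction is polar_angle + 90 deg; the
        # major axis sits `azimuth` degrees off that tangent
        phi = pa + np.pi / 2.0 + np.radians(canal.azimuth)
        ux, uy = np.cos(phi), np.sin(phi)
        dx = x - cx_mm
        dy = y - cy_mm
        u = dx * ux + dy * uy
        v = -dx * uy + dy * ux
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        n_rendered = int(np.sum(inside))
        if n_rendered < 8:
            raise ValueError(
                f"canal renders to only {n_rendered} px; decrease pixel_pitch"
            )
        raster[inside] = _KIND_LABEL[canal.kind]
        records.append({
            "x_px": float(c + cx_mm / pitch),
            "y_px": float(c - cy_mm / pitch),
            "radial_mm": canal.radial_position,
            "polar_deg": canal.polar_angle,
            "tilt_deg": canal.tilt,
            "azimuth_deg": canal.azimuth,
            "canal_radius_mm": canal.canal_radius,
            "aspect_ratio": canal.aspect_ratio,
            "kind": canal.kind,
            "true_category": canal.true_category,
            "rendered_px": n_rendered,
        })

    truth = pd.DataFrame(records, columns=[
        "x_px", "y_px", "radial_mm", "polar_deg", "tilt_deg", "azimuth_deg",
        "canal_radius_mm", "aspect_ratio", "kind", "true_category", "rendered_px",
    ])
    section = SectionImage(raster=raster, pixel_pitch=pitch,
                           specimen_id=f"synthetic-{spec.rng_seed}",
                           element="synthetic")
    return section, truth


def _clear_of(cand: CanalTruth, placed: list[CanalTruth], margin: float) -> bool:
    """Conservative non-overlap test: center distance beyond summed semi-majors."""
    pa = np.radians(cand.polar_angle)
    cx = cand.radial_position * np.cos(pa)
    cy = cand.radial_position * np.sin(pa)
    a_c = cand.canal_radius * cand.aspect_ratio
    for other in placed:
        ob = np.radians(other.polar_angle)
        ox = other.radial_position * np.cos(ob)
        oy = other.radial_position * np.sin(ob)
        a_o = other.canal_radius * other.aspect_ratio
        if np.hypot(cx - ox, cy - oy) <= a_c + a_o + margin:
            return False
    return True


def ground_truth_li(truth: pd.DataFrame) -> float:
    """Laminarity index implied by the ground-truth categories (primary only)."""
    primary = truth[truth["kind"] == "primary"]
    if primary.empty:
        raise ValueError("no primary canals in ground truth")
    return float((primary["true_category"] == "circumferential").mean())


# ---------------------------------------------------------------------------
# ontogenetic series
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSeriesSpec:
    """Growth series with a power-law Zp-mass relation and beta-distributed LI.

    Laminarity declines logit-linearly along PC1 of the robustly standardized
    (mass, length, Zp) triple: logit(mu) = beta0 + beta1*PC1, LI ~
    Beta(mu*phi, (1-mu)*phi).  Defaults mirror a pigeon-like growth series:
    17 specimens spanning 15-563 g, humerus-like scaling (a = 1.76,
    log10 b = -3.52), length ~ mass^(1/3).
    """

    n_specimens: int = 17
    mass_range: tuple[float, float] = (15.0, 563.0)   # g
    true_a: float = 1.76
    true_b: float = -3.52           # log10 intercept
    length_exponent: float = 1.0 / 3.0
    length_coef: float = 12.6       # mm at 1 g; ~100 mm at adult mass
    zp_noise_sd: float = 0.0        # log10 units
    beta0: float = -1.283           # logit-scale intercept
    beta1: float = -0.249           # logit-scale slope on PC1
    precision: float = 50.0         # beta-distribution phi
    rng_seed: int = 0
    element: str = "humerus"

    def __post_init__(self):
        if self.n_specimens < 3:
            raise ValueError("need at least 3 specimens")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")
        lo, hi = self.mass_range
        if not 0 < lo < hi:
            raise ValueError("mass_range must be increasing and positive")


def generate_ontogenetic_series(spec: SyntheticSeriesSpec) -> pd.DataFrame:
    """Simulate one growth series; identical seeds give identical tables."""
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.mass_range
    mass = np.logspace(np.log10(lo), np.log10(hi), spec.n_specimens)
    length = spec.length_coef * mass ** spec.length_exponent
    log_zp = spec.true_b + spec.true_a * np.log10(mass)
    if spec.zp_noise_sd > 0:
        log_zp = log_zp + rng.normal(0.0, spec.zp_noise_sd, size=mass.size)
    zp = 10.0 ** log_zp

    std = ontostats.robust_standardize(
        np.column_stack([mass, length, zp]), columns=("mass", "length", "zp"))
    pca = ontostats.fit_pca(std)
    pc1 = pca.scores[:, 0]
    mu = special.expit(spec.beta0 + spec.beta1 * pc1)
    li = rng.beta(mu * spec.precision, (1.0 - mu) * spec.precision)
    # beta draws are open-interval almost surely; guard against underflow
    eps = 1e-9
    li = np.clip(li, eps, 1.0 - eps)

    return pd.DataFrame({
        "specimen_id": [f"S{i:03d}" for i in range(spec.n_specimens)],
        "element": spec.element,
        "mass_g": mass,
        "length_mm": length,
        "zp_mm3": zp,
        "pc1_true": pc1,
        "li": li,
    })
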