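"""Raster + sidecar I/O for labelled bone sections.

A section on disk is an 8-bit label image (PNG or TIFF; 0 background, 1 bone,
2 primary canal, 3 secondary canal, 4 resorption space) plus a JSON sidecar
``<stem>.json`` carrying pixel pitch (mm/px), the anatomical orientation map,
limb type and identifiers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .xgeom import SectionImage

SIDECAR_SUFFIX = ".json"


def write_section(section: SectionImage, path: str | Path,
                  seed: int | None = None) -> Path:
    """Write the label raster and its sidecar; returns the raster path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raster = np.asarray(section.raster, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    else:
        Image.fromarray(raster, mode="L").save(path)
    sidecar = {
        "pixel_pitch_mm": section.pixel_pitch,
        "orientation_map": dict(section.orientation_map),
        "limb": section.limb,
        "specimen_id": section.specimen_id,
        "element": section.element,
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    path.with_suffix(SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=2))
    return path


def read_section(path: str | Path) -> SectionImage:
    """Read a labelled raster and its JSON sidecar back into a SectionImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raster = tifffile.imread(path)
    else:
        raster = np.asarray(Image.open(path))
    sidecar_path = path.with_suffix(SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    return SectionImage(
        raster=np.asarray(raster, dtype=np.uint8),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        orientation_map=meta.get("orientation_map", {
            "up": "cranial", "right": "dorsal", "down": "caudal", "left": "ventral",
        }),
        limb=meta.get("limb", "forelimb"),
        specimen_id=meta.get("specimen_id", path.stem),
        element=meta.get("element", ""),
    )
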