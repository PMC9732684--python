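"""Mucosal compartment geometry: epithelium, subepithelial band, lamina propria.

The mucosa is partitioned into three exclusive zones derived from two masks:

* epithelium — the segmented epithelial layer;
* subepithelial band — the zone within a fixed geometric distance (default
  5 micrometres) below the basement membrane, i.e. the Euclidean dilation of
  the epithelium minus the epithelium itself, clipped to tissue;
* lamina propria — the remaining tissue.

Distances are physical: the dilation radius is specified in micrometres and
converted through the raster's microns-per-pixel scale, with the threshold
applied to the real-valued Euclidean distance transform (no rounding of the
radius to whole pixels, so the band width does not depend on resolution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .staining import BinaryMask

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_EPITHELIUM",
    "LABEL_BAND",
    "LABEL_LAMINA",
    "LABEL_NAMES",
    "CompartmentMaps",
    "expand_epithelium",
    "build_compartments",
]

LABEL_BACKGROUND = 0
LABEL_EPITHELIUM = 1
LABEL_BAND = 2
LABEL_LAMINA = 3

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_EPITHELIUM: "epithelium",
    LABEL_BAND: "subepithelial_band",
    LABEL_LAMINA: "lamina_propria",
}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}

COMPARTMENT_FORMAT_VERSION = 1


class CompartmentPreconditionError(ValueError):
    """Input masks violate the compartment preconditions."""


@dataclass
class CompartmentMaps:
    """Exclusive compartment label raster with areas in physical units.

    ``labels`` holds {0: background, 1: epithelium, 2: subepithelial band,
    3: lamina propria}; the three tissue labels partition the tissue mask
    exactly.  ``areas_mm2`` maps label names to areas (pixel count x mpp^2).
    """

    labels: np.ndarray
    microns_per_pixel: float
    areas_mm2: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def tissue_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    def mask(self, name: str) -> np.ndarray:
        return self.labels == NAME_LABELS[name]

    def save(self, path: str | Path) -> None:
        """Single-channel PNG label image + JSON sidecar with the areas."""
        path = Path(path)
        Image.fromarray(self.labels.astype(np.uint8)).save(path)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps({
            "microns_per_pixel": self.microns_per_pixel,
            "areas_mm2": self.areas_mm2,
            "format_version": COMPARTMENT_FORMAT_VERSION,
        }))

    @classmethod
    def load(cls, path: str | Path) -> "CompartmentMaps":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        labels = np.asarray(Image.open(path)).astype(np.uint8)
        return cls(labels=labels, microns_per_pixel=float(meta["microns_per_pixel"]),
                   areas_mm2=dict(meta["areas_mm2"]))


def expand_epithelium(epithelium: BinaryMask, distance_um: float = 5.0) -> BinaryMask:
    """Euclidean dilation of the epithelium mask by a physical distance.

    A pixel belongs to the output iff its Euclidean distance (in micrometres,
    via the mask's mpp) to the epithelium set is <= ``distance_um``; the
    output is therefore always a superset of the input and ``distance_um=0``
    is the identity.
    """
    if distance_um < 0:
        raise ValueError("expansion distance must be >= 0")
    mask = epithelium.mask
    if distance_um == 0 or not mask.any():
        return BinaryMask(mask=mask.copy(), microns_per_pixel=epithelium.microns_per_pixel,
                          role="expanded_epithelium")
    dist_px = ndimage.distance_transform_edt(~mask)
    out = dist_px * epithelium.microns_per_pixel <= distance_um
    return BinaryMask(mask=out, microns_per_pixel=epithelium.microns_per_pixel,
                      role="expanded_epithelium")


def build_compartments(
    tissue: BinaryMask, epithelium: BinaryMask, expanded: BinaryMask
) -> CompartmentMaps:
    """Assemble the exclusive compartment label map.

    band = (expanded \\ epithelium) ∩ tissue;
    lamina propria = tissue \\ expanded.  Where the expansion would leave
    tissue (biopsy edge / lumen) it is clipped to tissue, so the three labels
    partition the tissue mask exactly.
    """
    if tissue.shape != epithelium.shape or tissue.shape != expanded.shape:
        raise CompartmentPreconditionError("masks must share one raster geometry")
    if np.any(epithelium.mask & ~tissue.mask):
        raise CompartmentPreconditionError("epithelium mask is not a subset of tissue")
    if np.any(epithelium.mask & ~expanded.mask):
        raise CompartmentPreconditionError("expanded mask must contain the epithelium")
    labels = np.zeros(tissue.shape, dtype=np.uint8)
    epi = epithelium.mask & tissue.mask
    band = expanded.mask & ~epithelium.mask & tissue.mask
    lamina = tissue.mask & ~expanded.mask
    labels[epi] = LABEL_EPITHELIUM
    labels[band] = LABEL_BAND
    labels[lamina] = LABEL_LAMINA
    mpp = tissue.microns_per_pixel
    px_area = (mpp / 1000.0) ** 2
    areas = {LABEL_NAMES[k]: float((labels == k).sum()) * px_area
             for k in (LABEL_EPITHELIUM, LABEL_BAND, LABEL_LAMINA)}
    areas["tissue"] = float(tissue.mask.sum()) * px_area
    return CompartmentMaps(labels=labels, microns_per_pixel=mpp, areas_mm2=areas)
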