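"""Per-biopsy compartmental counts and the normalisation scheme.

Each classified cell is assigned to exactly one compartment by the label of
the compartment map at its nucleus centroid (cells straddling the basement
membrane take the centroid's side; detections over background are excluded).
Counts obey the subtraction identities of the compartment construction:
subepithelial = (epithelium + 5 um band) - epithelium, lamina propria =
whole mucosa - expanded region, so the three compartments always sum to the
whole-mucosa count exactly.

Normalised measures follow pathology convention: intraepithelial and
subepithelial positives per 100 epithelial cells, lamina-propria positives
per mm^2 of mucosa.  A zero denominator flags the measure as missing (None),
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .cells import CellDetection
from .compartments import LABEL_NAMES, CompartmentMaps

__all__ = [
    "BiopsyQuant",
    "assign_compartment",
    "assign_compartments",
    "tabulate_biopsy",
    "normalize_counts",
    "compute_gd_cd3_ratio",
    "quants_to_frame",
]


class UnclassifiedDetectionError(ValueError):
    """A detection reached tabulation without a class label."""


class BiopsyMismatchError(ValueError):
    """Ratio requested across two different biopsies."""


@dataclass
class BiopsyQuant:
    """Counts and normalised measures for one biopsy and one stain.

    Raw counts: positives per compartment plus the total (positive +
    negative) epithelial cell count used as the per-100 denominator.
    Derived measures are None until :func:`normalize_counts` fills them and
    stay None when their denominator is zero.
    """

    biopsy_id: str
    stain: str
    epithelial_positive: int = 0
    epithelial_total_cells: int = 0
    subepithelial_positive: int = 0
    lamina_positive: int = 0
    mucosa_area_mm2: float = 0.0
    iel_per_100: float | None = None
    sub_per_100: float | None = None
    lamina_per_mm2: float | None = None

    @property
    def whole_mucosa_positive(self) -> int:
        return (self.epithelial_positive + self.subepithelial_positive
                + self.lamina_positive)


def assign_compartment(detection: CellDetection, maps: CompartmentMaps) -> str:
    """Compartment label at the nucleus centroid pixel.

    Returns one of {background, epithelium, subepithelial_band,
    lamina_propria}; callers exclude background detections from all counts.
    """
    x, y = detection.centroid
    row, col = int(round(y)), int(round(x))
    h, w = maps.shape
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError(f"centroid ({x:.1f}, {y:.1f}) outside raster {maps.shape}")
    return LABEL_NAMES[int(maps.labels[row, col])]


def assign_compartments(detections: list[CellDetection],
                        maps: CompartmentMaps) -> list[CellDetection]:
    for det in detections:
        det.compartment = assign_compartment(det, maps)
    return detections


def tabulate_biopsy(detections: list[CellDetection], maps: CompartmentMaps,
                    stain: str, biopsy_id: str = "") -> BiopsyQuant:
    """Tally classified detections into the per-compartment count scheme.

    Artefacts are excluded from every count; the epithelial total cell count
    (the per-100 denominator) is positives + negatives labelled epithelium.
    Raises when any detection is still unclassified.
    """
    if any(d.cell_class is None for d in detections):
        raise UnclassifiedDetectionError("tabulation requires classified detections")
    for det in detections:
        if det.compartment is None:
            det.compartment = assign_compartment(det, maps)
    q = BiopsyQuant(biopsy_id=biopsy_id, stain=stain,
                    mucosa_area_mm2=float(maps.areas_mm2.get(
                        "tissue",
                        sum(maps.areas_mm2.get(LABEL_NAMES[k], 0.0) for k in (1, 2, 3)))))
    for det in detections:
        if det.cell_class == "artefact" or det.compartment == "background":
            continue
        comp = det.compartment
        if comp == "epithelium":
            q.epithelial_total_cells += 1
            if det.cell_class == "positive":
                q.epithelial_positive += 1
        elif det.cell_class == "positive":
            if comp == "subepithelial_band":
                q.subepithelial_positive += 1
            elif comp == "lamina_propria":
                q.lamina_positive += 1
    return normalize_counts(q)


def normalize_counts(q: BiopsyQuant) -> BiopsyQuant:
    """Fill the derived measures; zero denominators yield None (missing)."""
    iel = (100.0 * q.epithelial_positive / q.epithelial_total_cells
           if q.epithelial_total_cells > 0 else None)
    sub = (100.0 * q.subepithelial_positive / q.epithelial_total_cells
           if q.epithelial_total_cells > 0 else None)
    lam = (q.lamina_positive / q.mucosa_area_mm2
           if q.mucosa_area_mm2 > 0 else None)
    return replace(q, iel_per_100=iel, sub_per_100=sub, lamina_per_mm2=lam)


def compute_gd_cd3_ratio(gd: BiopsyQuant, cd3: BiopsyQuant) -> dict:
    """Per-compartment gamma-delta / CD3 ratio (%) on matching normalised
    measures from parallel sections of the same biopsy.

    Returns {compartment: ratio or None}; a ratio is missing when the CD3
    measure is zero or missing.
    """
    if gd.biopsy_id != cd3.biopsy_id:
        raise BiopsyMismatchError(
            f"biopsy ids differ: {gd.biopsy_id!r} vs {cd3.biopsy_id!r}")
    out = {}
    for comp, g, c in (
        ("epithelium", gd.iel_per_100, cd3.iel_per_100),
        ("subepithelial_band", gd.sub_per_100, cd3.sub_per_100),
        ("lamina_propria", gd.lamina_per_mm2, cd3.lamina_per_mm2),
    ):
        out[comp] = None if (g is None or c is None or c == 0) else 100.0 * g / c
    return out


def quants_to_frame(quants: list[BiopsyQuant]) -> pd.DataFrame:
    """BiopsyQuant rows as a tidy table (one row per quant)."""
    return pd.DataFrame([{
        "biopsy_id": q.biopsy_id, "stain": q.stain,
        "epithelial_positive": q.epithelial_positive,
        "epithelial_total_cells": q.epithelial_total_cells,
        "subepithelial_positive": q.subepithelial_positive,
        "lamina_positive": q.lamina_positive,
        "whole_mucosa_positive": q.whole_mucosa_positive,
        "mucosa_area_mm2": q.mucosa_area_mm2,
        "iel_per_100": q.iel_per_100,
        "sub_per_100": q.sub_per_100,
        "lamina_per_mm2": q.lamina_per_mm2,
    } for q in quants])
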