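"""Nucleus detection, area filtering, cell expansion and classification.

Detection runs on the hematoxylin optical-density channel (every nucleus is
counterstained): the OD map is Gaussian-smoothed, local maxima above a
threshold become markers, and marker-based watershed on the inverted OD
landscape delineates one nucleus region per marker.  This re-creates the
contract of a pretrained star-convex detector with a deterministic,
desk-scale classical pipeline; the reference settings map directly
(requested pixel size -> the scale at which nucleus areas are evaluated,
probability threshold -> minimum absorbed-fraction score at a peak).

Nucleus areas are always evaluated in px^2 at the requested reference pixel
size (default 0.225 um/px), so the 125-3000 px^2 inclusion bounds mean the
same physical area (6.33-151.9 um^2) at any native image resolution.

Each retained nucleus is expanded by a fixed physical distance (default
1.5 um) to a cell region; overlapping expansions are split by the
nearest-nucleus (Voronoi) rule.  A seeded random-forest classifier over the
per-cell feature vector assigns one of three classes: stain-positive cell,
stain-negative cell, or artefact.  Artefacts are excluded from all counts
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed
from sklearn.ensemble import RandomForestClassifier

from .staining import StainMaps

__all__ = [
    "DetectionSettings",
    "CellDetection",
    "CellClassifier",
    "FEATURE_NAMES",
    "CLASSES",
    "detect_nuclei",
    "filter_by_area",
    "expand_cells",
    "train_cell_classifier",
    "classify_cells",
    "detections_to_frame",
]

CLASSES = ("positive", "negative", "artefact")

FEATURE_NAMES = (
    "dab_mean_nucleus",
    "dab_max_nucleus",
    "dab_mean_cell",
    "dab_max_cell",
    "hematoxylin_mean_nucleus",
    "nucleus_area_um2",
    "eccentricity",
    "solidity",
)

CLASSIFIER_FORMAT_VERSION = 1


class DegenerateTrainingError(ValueError):
    """Training set contains fewer than two cell classes."""


class FeatureSchemaError(ValueError):
    """Detections and classifier use different feature schemas."""


@dataclass
class DetectionSettings:
    """Detection and measurement settings.

    ``requested_pixel_size`` (um/px) fixes the reference scale for the
    nucleus-area bounds; ``detection_threshold`` is the minimum
    absorbed-light fraction (1 - 10^-OD) at a peak; ``nucleus_od_threshold``
    separates nucleus foreground from the tissue wash on the smoothed
    hematoxylin OD map.
    """

    requested_pixel_size: float = 0.225
    detection_threshold: float = 0.01
    cell_expansion_um: float = 1.5
    min_nucleus_area_px: float = 125.0
    max_nucleus_area_px: float = 3000.0
    min_peak_separation_um: float = 4.0
    smooth_sigma_um: float = 1.5
    nucleus_od_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.min_nucleus_area_px < self.max_nucleus_area_px:
            raise ValueError("need 0 < min nucleus area < max nucleus area")
        if self.cell_expansion_um < 0:
            raise ValueError("cell expansion must be >= 0")
        if not self.requested_pixel_size > 0:
            raise ValueError("requested pixel size must be > 0")


@dataclass
class CellDetection:
    """One detected cell.

    Pixel coordinates are native-raster (x rightward, y downward);
    ``nucleus_area_ref_px`` is the nucleus area in px^2 at the requested
    reference pixel size.  ``cell_class`` stays None until classification.
    """

    centroid: tuple[float, float]  # (x, y)
    nucleus_pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    nucleus_area_um2: float
    nucleus_area_ref_px: float
    cell_pixels: tuple[np.ndarray, np.ndarray] | None = None
    features: dict = field(default_factory=dict)
    cell_class: str | None = None
    compartment: str | None = None

    def feature_vector(self) -> np.ndarray:
        try:
            return np.array([self.features[k] for k in FEATURE_NAMES], dtype=float)
        except KeyError as exc:
            raise FeatureSchemaError(f"missing feature {exc}") from exc


def detect_nuclei(stains: StainMaps, settings: DetectionSettings | None = None
                  ) -> list[CellDetection]:
    """Detect candidate nuclei on the hematoxylin OD channel.

    Deterministic: smoothed-OD peak detection followed by marker-based
    watershed.  Peaks whose absorbed-fraction score falls below
    ``detection_threshold`` are discarded.  An empty list is a valid result.
    """
    if settings is None:
        settings = DetectionSettings()
    mpp = stains.microns_per_pixel
    sigma = settings.smooth_sigma_um / mpp
    smoothed = ndimage.gaussian_filter(stains.hematoxylin, sigma)
    fg = smoothed > settings.nucleus_od_threshold
    if not fg.any():
        return []
    min_dist = max(1, int(round(settings.min_peak_separation_um / mpp)))
    coords = peak_local_max(smoothed, min_distance=min_dist, labels=fg,
                            exclude_border=False)
    if coords.size == 0:
        return []
    score = 1.0 - np.power(10.0, -smoothed[coords[:, 0], coords[:, 1]])
    coords = coords[score >= settings.detection_threshold]
    if coords.size == 0:
        return []
    markers = np.zeros(smoothed.shape, dtype=np.int32)
    markers[coords[:, 0], coords[:, 1]] = np.arange(1, len(coords) + 1)
    labels = watershed(-smoothed, markers=markers, mask=fg)
    scale = (mpp / settings.requested_pixel_size) ** 2
    detections: list[CellDetection] = []
    for prop in regionprops(labels):
        rows, cols = prop.coords[:, 0], prop.coords[:, 1]
        cy, cx = prop.centroid
        detections.append(CellDetection(
            centroid=(float(cx), float(cy)),
            nucleus_pixels=(rows, cols),
            nucleus_area_um2=float(prop.area) * mpp**2,
            nucleus_area_ref_px=float(prop.area) * scale,
            features={
                "nucleus_area_um2": float(prop.area) * mpp**2,
                "eccentricity": float(prop.eccentricity),
                "solidity": float(prop.solidity),
            },
        ))
    return detections


def filter_by_area(detections: list[CellDetection],
                   settings: DetectionSettings | None = None) -> list[CellDetection]:
    """Keep detections whose nucleus area (px^2 at the reference scale) lies
    inside the inclusive bounds; order preserved.  Pure and idempotent."""
    if settings is None:
        settings = DetectionSettings()
    return [d for d in detections
            if settings.min_nucleus_area_px <= d.nucleus_area_ref_px
            <= settings.max_nucleus_area_px]


def expand_cells(detections: list[CellDetection], stains: StainMaps,
                 settings: DetectionSettings | None = None) -> list[CellDetection]:
    """Expand each nucleus by the physical cell-expansion distance and
    measure the feature vector over nucleus and cell regions.

    Overlapping expansions are split by the nearest-nucleus rule, so cell
    regions of distinct detections are always disjoint.
    """
    if settings is None:
        settings = DetectionSettings()
    mpp = stains.microns_per_pixel
    shape = stains.shape
    labels = np.zeros(shape, dtype=np.int32)
    for i, det in enumerate(detections, start=1):
        labels[det.nucleus_pixels] = i
    dist_px = settings.cell_expansion_um / mpp
    expanded = expand_labels(labels, distance=dist_px) if dist_px > 0 else labels
    for i, det in enumerate(detections, start=1):
        cell_rows, cell_cols = np.nonzero(expanded == i)
        det.cell_pixels = (cell_rows, cell_cols)
        nr, nc = det.nucleus_pixels
        dab_nuc = stains.dab[nr, nc]
        dab_cell = stains.dab[cell_rows, cell_cols]
        det.features.update({
            "dab_mean_nucleus": float(dab_nuc.mean()),
            "dab_max_nucleus": float(dab_nuc.max()),
            "dab_mean_cell": float(dab_cell.mean()),
            "dab_max_cell": float(dab_cell.max()),
            "hematoxylin_mean_nucleus": float(stains.hematoxylin[nr, nc].mean()),
        })
    return detections


@dataclass
class CellClassifier:
    """Seeded three-class random-forest over the cell feature vector."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...] = FEATURE_NAMES
    format_version: int = CLASSIFIER_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": self.format_version,
                     "feature_names": self.feature_names,
                     "forest": self.forest}, path)

    @classmethod
    def load(cls, path: str | Path) -> "CellClassifier":
        blob = joblib.load(path)
        if blob.get("format_version") != CLASSIFIER_FORMAT_VERSION:
            raise ValueError(f"unsupported classifier format: {blob.get('format_version')}")
        return cls(forest=blob["forest"], feature_names=tuple(blob["feature_names"]))


def train_cell_classifier(detections: list[CellDetection],
                          labels: list[str] | None = None,
                          seed: int = 0) -> CellClassifier:
    """Train the three-class cell classifier on labelled detections.

    ``labels`` defaults to the detections' own ``cell_class`` attributes
    (e.g. set from ground truth).  At least two of the three classes must
    be present.  Identical seed and data give identical predictions.
    """
    if labels is None:
        labels = [d.cell_class for d in detections]
    labels = list(labels)
    if any(lab is None for lab in labels):
        raise ValueError("all training detections need a class label")
    if len(set(labels)) < 2:
        raise DegenerateTrainingError(
            "training set must contain at least two cell classes")
    x = np.stack([d.feature_vector() for d in detections])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values in training set")
    forest = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    forest.fit(x, labels)
    return CellClassifier(forest=forest)


def classify_cells(detections: list[CellDetection],
                   classifier: CellClassifier) -> list[CellDetection]:
    """Assign each detection exactly one class from the classifier."""
    if tuple(classifier.feature_names) != FEATURE_NAMES:
        raise FeatureSchemaError("classifier was trained on a different feature schema")
    if not detections:
        return detections
    x = np.stack([d.feature_vector() for d in detections])
    pred = classifier.forest.predict(x)
    for det, cls_ in zip(detections, pred):
        det.cell_class = str(cls_)
    return detections


def label_detections_from_truth(detections: list[CellDetection],
                                truth_cells: pd.DataFrame,
                                tol_px: float = 6.0) -> list[CellDetection]:
    """Label detections with the class of the nearest planted cell.

    One-to-one assignment by ascending centroid distance; detections with no
    planted cell within ``tol_px`` keep ``cell_class=None``.  Intended for
    building classifier training sets from synthetic ground truth.
    """
    if not detections or truth_cells.empty:
        return detections
    tx = truth_cells[["x", "y"]].to_numpy(float)
    dx = np.array([d.centroid for d in detections])
    dist = np.linalg.norm(tx[:, None, :] - dx[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_t, used_d = set(), set()
    classes = truth_cells["cell_class"].to_numpy()
    for ti, di in order:
        if dist[ti, di] > tol_px:
            break
        if ti in used_t or di in used_d:
            continue
        detections[di].cell_class = str(classes[ti])
        used_t.add(ti)
        used_d.add(di)
    return detections


def detections_to_frame(detections: list[CellDetection]) -> pd.DataFrame:
    """One row per cell: id, centroid, area, class, compartment, features."""
    rows = []
    for i, d in enumerate(detections):
        row = {"id": i, "x": d.centroid[0], "y": d.centroid[1],
               "nucleus_area_um2": d.nucleus_area_um2,
               "nucleus_area_ref_px": d.nucleus_area_ref_px,
               "class": d.cell_class, "compartment": d.compartment}
        row.update({k: d.features.get(k) for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
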