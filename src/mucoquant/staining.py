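"""Stain separation and tissue/epithelium segmentation for H-DAB images.

Immunohistochemistry slides stained with a hematoxylin counterstain and the
DAB chromogen are modelled with the Beer-Lambert law: each stain absorbs
light proportionally to its local concentration, so in optical-density (OD)
space the pixel value is a linear mixture of per-stain unit "colour" vectors.
Colour deconvolution inverts that mixture, yielding one OD map per stain.
The hematoxylin map drives nucleus detection (all nuclei are counterstained)
and the DAB map carries the immunostain signal (CD3 or TCR-delta here).

Segmentation produces two binary masks in the same raster geometry:

* the *tissue* mask (total absorbance above background), and
* the *epithelium* mask, either rasterised from polygon annotations or
  predicted by a trainable per-pixel classifier over local image features.

All geometry is calibrated: every raster carries a microns-per-pixel scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import morphology
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "STAIN_HEMATOXYLIN",
    "STAIN_DAB",
    "CalibratedImage",
    "StainMaps",
    "BinaryMask",
    "SegmenterSettings",
    "EpitheliumSegmenter",
    "default_stain_matrix",
    "complete_stain_matrix",
    "rgb_to_od",
    "od_to_rgb",
    "separate_stains",
    "segment_tissue",
    "train_epithelium_segmenter",
    "predict_epithelium",
    "load_annotation_polygons",
]

# Standard published H-DAB stain vectors (RGB optical-density space),
# normalised to unit length.  Deconvolution was "manually set" per stain in
# the original workflow, so these are defaults, not constants of nature.
STAIN_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
STAIN_HEMATOXYLIN = STAIN_HEMATOXYLIN / np.linalg.norm(STAIN_HEMATOXYLIN)
STAIN_DAB = np.array([0.27, 0.57, 0.78])
STAIN_DAB = STAIN_DAB / np.linalg.norm(STAIN_DAB)

#: intensity floor applied before the base-10 log, avoids log(0)
_INTENSITY_FLOOR = 1.0

MASK_FORMAT_VERSION = 1
MODEL_FORMAT_VERSION = 1


class CollinearStainsError(ValueError):
    """Stain vectors are (nearly) collinear; the unmixing matrix is singular."""


class AnnotationError(ValueError):
    """A polygon annotation could not be parsed or rasterised."""


class AlignmentError(ValueError):
    """Training images and annotation masks do not align."""


class DegenerateTrainingError(ValueError):
    """Training annotations contain a single class only."""


@dataclass
class CalibratedImage:
    """8-bit RGB raster with a physical pixel size.

    Parameters
    ----------
    rgb : ndarray, shape (H, W, 3), uint8
    microns_per_pixel : float
        Physical edge length of one pixel, in micrometres.
    ident : str
        Free-form identifier (file stem, biopsy id, ...).
    """

    rgb: np.ndarray
    microns_per_pixel: float
    ident: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("image must be an (H, W, 3) RGB array")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def save(self, path: str | Path) -> None:
        """Write the raster (PNG or TIFF by extension) plus a JSON sidecar
        carrying ``microns_per_pixel``."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            tifffile.imwrite(path, self.rgb.astype(np.uint8))
        else:
            Image.fromarray(self.rgb.astype(np.uint8)).save(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"microns_per_pixel": self.microns_per_pixel, "ident": self.ident})
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibratedImage":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"missing microns-per-pixel sidecar for {path.name}: {sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            rgb = tifffile.imread(path)
        else:
            rgb = np.asarray(Image.open(path).convert("RGB"))
        return cls(rgb=rgb, microns_per_pixel=float(meta["microns_per_pixel"]),
                   ident=str(meta.get("ident", path.stem)))


@dataclass
class StainMaps:
    """Per-pixel optical densities for hematoxylin and DAB.

    Negative unmixing solutions are clamped to zero, so both maps are >= 0.
    ``stain_matrix`` is the full 3x3 matrix used (columns = unit vectors in
    RGB-OD space; third column is the completed residual vector).
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    stain_matrix: np.ndarray
    microns_per_pixel: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape


@dataclass
class BinaryMask:
    """Boolean raster with physical scale and a role tag."""

    mask: np.ndarray
    microns_per_pixel: float
    role: str = "tissue"  # tissue | epithelium | expanded_epithelium

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def area_mm2(self) -> float:
        """Mask area in mm^2 (pixel count x mpp^2)."""
        return float(self.mask.sum()) * (self.microns_per_pixel / 1000.0) ** 2

    def save(self, path: str | Path) -> None:
        """Write as single-channel PNG (0/255) + JSON sidecar."""
        path = Path(path)
        Image.fromarray((self.mask.astype(np.uint8)) * 255).save(path)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps({
            "microns_per_pixel": self.microns_per_pixel,
            "role": self.role,
            "format_version": MASK_FORMAT_VERSION,
        }))

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        arr = np.asarray(Image.open(path)) > 127
        return cls(mask=arr, microns_per_pixel=float(meta["microns_per_pixel"]),
                   role=str(meta.get("role", "tissue")))


# ---------------------------------------------------------------------------
# Colour deconvolution
# ---------------------------------------------------------------------------

def default_stain_matrix() -> np.ndarray:
    """H-DAB stain matrix: columns (hematoxylin, DAB), shape (3, 2)."""
    return np.column_stack([STAIN_HEMATOXYLIN, STAIN_DAB])


def complete_stain_matrix(matrix: np.ndarray) -> np.ndarray:
    """Return a full 3x3 stain matrix with unit columns.

    A two-column matrix is completed with the normalised cross product of its
    columns (the standard residual channel of colour deconvolution).  Raises
    :class:`CollinearStainsError` when the columns are not independent.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape == (3, 3):
        full = m.copy()
    elif m.shape == (3, 2):
        third = np.cross(m[:, 0], m[:, 1])
        norm = np.linalg.norm(third)
        if norm < 1e-8:
            raise CollinearStainsError("stain vectors are collinear")
        full = np.column_stack([m, third / norm])
    else:
        raise ValueError(f"stain matrix must be (3, 2) or (3, 3), got {m.shape}")
    norms = np.linalg.norm(full, axis=0)
    if np.any(norms < 1e-12):
        raise CollinearStainsError("zero-length stain vector")
    full = full / norms
    if abs(np.linalg.det(full)) < 1e-6:
        raise CollinearStainsError("stain matrix is singular (collinear vectors)")
    return full


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density: OD = -log10(max(I, 1) / 255)."""
    arr = np.maximum(np.asarray(rgb, dtype=float), _INTENSITY_FLOOR)
    return -np.log10(arr / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse Beer-Lambert transmittance: I = 255 * 10^(-OD), rounded to uint8."""
    arr = 255.0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def separate_stains(
    image: CalibratedImage, stain_matrix: np.ndarray | None = None
) -> StainMaps:
    """Unmix an H-DAB image into hematoxylin and DAB OD maps.

    The per-pixel RGB optical density vector is projected onto stain space by
    the inverse of the (completed) stain matrix; negative concentrations are
    clamped to 0.
    """
    if stain_matrix is None:
        stain_matrix = default_stain_matrix()
    full = complete_stain_matrix(stain_matrix)
    od = rgb_to_od(image.rgb).reshape(-1, 3)
    conc = od @ np.linalg.inv(full).T
    conc = np.maximum(conc, 0.0)
    h, w = image.shape
    return StainMaps(
        hematoxylin=conc[:, 0].reshape(h, w),
        dab=conc[:, 1].reshape(h, w),
        stain_matrix=full,
        microns_per_pixel=image.microns_per_pixel,
    )


# ---------------------------------------------------------------------------
# Tissue segmentation
# ---------------------------------------------------------------------------

def segment_tissue(
    image: CalibratedImage,
    background_threshold: float = 0.05,
    min_area_mm2: float = 0.001,
) -> BinaryMask:
    """Mask of tissue pixels: total optical density above background.

    Total OD is the sum of the three RGB channel ODs.  Holes are filled and
    connected components smaller than ``min_area_mm2`` removed.  An empty
    mask is a valid result (blank image).
    """
    total_od = rgb_to_od(image.rgb).sum(axis=2)
    mask = total_od > background_threshold
    mask = ndimage.binary_fill_holes(mask)
    min_px = int(np.ceil(min_area_mm2 / (image.microns_per_pixel / 1000.0) ** 2))
    if min_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    return BinaryMask(mask=mask, microns_per_pixel=image.microns_per_pixel, role="tissue")


# ---------------------------------------------------------------------------
# Trainable epithelium segmenter
# ---------------------------------------------------------------------------

@dataclass
class SegmenterSettings:
    """Feature and training settings for the per-pixel epithelium classifier.

    Features are computed per pixel from the stain OD maps and grayscale
    intensity: raw values plus Gaussian means and local standard deviations
    at ``scales_um`` (micrometre sigmas, converted per image via its mpp).
    """

    scales_um: tuple[float, ...] = (1.0, 3.0, 6.0)
    n_estimators: int = 60
    max_samples_per_image: int = 40_000
    min_component_area_mm2: float = 0.0002
    seed: int = 0
    stain_matrix: np.ndarray | None = None


def _feature_stack(image: CalibratedImage, settings: SegmenterSettings) -> np.ndarray:
    """(H, W, F) per-pixel feature stack."""
    stains = separate_stains(image, settings.stain_matrix)
    gray = np.asarray(image.rgb, dtype=float).mean(axis=2) / 255.0
    base = [stains.hematoxylin, stains.dab, gray]
    feats = list(base)
    for s_um in settings.scales_um:
        sigma = s_um / image.microns_per_pixel
        for b in base:
            mean = ndimage.gaussian_filter(b, sigma)
            sq = ndimage.gaussian_filter(b * b, sigma)
            feats.append(mean)
            feats.append(np.sqrt(np.maximum(sq - mean**2, 0.0)))
    return np.stack(feats, axis=-1)


@dataclass
class EpitheliumSegmenter:
    """Seeded random-forest per-pixel classifier with the same mask contract
    as the original deep segmentation stage (image in, epithelium mask out)."""

    forest: RandomForestClassifier
    settings: SegmenterSettings
    format_version: int = MODEL_FORMAT_VERSION
    trained: bool = True

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": self.format_version,
                     "settings": self.settings, "forest": self.forest}, path)

    @classmethod
    def load(cls, path: str | Path) -> "EpitheliumSegmenter":
        blob = joblib.load(path)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {blob.get('format_version')}")
        return cls(forest=blob["forest"], settings=blob["settings"])


def train_epithelium_segmenter(
    images: list[CalibratedImage],
    epithelium_masks: list[BinaryMask],
    settings: SegmenterSettings | None = None,
) -> EpitheliumSegmenter:
    """Train the per-pixel epithelium classifier on annotated images.

    Pixels inside each annotation mask are the positive class; all other
    pixels the negative class.  Pixels are subsampled per image (seeded) to
    keep training desk-scale.  Identical seed and inputs give an identical
    model and therefore identical predictions.
    """
    if settings is None:
        settings = SegmenterSettings()
    if len(images) == 0 or len(images) != len(epithelium_masks):
        raise AlignmentError("need >= 1 image with one annotation mask each")
    rng = np.random.default_rng(settings.seed)
    xs, ys = [], []
    for img, ann in zip(images, epithelium_masks):
        if ann.shape != img.shape:
            raise AlignmentError(
                f"annotation {ann.shape} does not align with image {img.shape}")
        feats = _feature_stack(img, settings).reshape(-1, _n_features(settings))
        labels = ann.mask.reshape(-1).astype(np.int8)
        n = labels.size
        take = min(settings.max_samples_per_image, n)
        idx = rng.choice(n, size=take, replace=False)
        xs.append(feats[idx])
        ys.append(labels[idx])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.unique(y).size < 2:
        raise DegenerateTrainingError(
            "annotations contain a single class; need both epithelium and background")
    forest = RandomForestClassifier(
        n_estimators=settings.n_estimators,
        random_state=settings.seed,
        n_jobs=1,
        min_samples_leaf=2,
    )
    forest.fit(x, y)
    return EpitheliumSegmenter(forest=forest, settings=settings)


def _n_features(settings: SegmenterSettings) -> int:
    return 3 + 6 * len(settings.scales_um)


def predict_epithelium(
    image: CalibratedImage,
    model: EpitheliumSegmenter,
    tissue: BinaryMask | None = None,
) -> BinaryMask:
    """Predict the epithelium mask for an image.

    Post-processing: holes filled, components below the settings' minimum
    area removed, and the mask intersected with the tissue mask (epithelium
    is mucosal tissue by definition).
    """
    if not getattr(model, "trained", False):
        raise ValueError("segmenter model is not trained")
    settings = model.settings
    feats = _feature_stack(image, settings).reshape(-1, _n_features(settings))
    pred = model.forest.predict(feats).reshape(image.shape).astype(bool)
    pred = ndimage.binary_fill_holes(pred)
    min_px = int(np.ceil(
        settings.min_component_area_mm2 / (image.microns_per_pixel / 1000.0) ** 2))
    if min_px > 1:
        pred = morphology.remove_small_objects(pred, max_size=min_px - 1)
    if tissue is None:
        tissue = segment_tissue(image)
    pred &= tissue.mask
    return BinaryMask(mask=pred, microns_per_pixel=image.microns_per_pixel,
                      role="epithelium")


# ---------------------------------------------------------------------------
# Polygon annotations (GeoJSON)
# ---------------------------------------------------------------------------

def load_annotation_polygons(
    source: str | Path | dict,
    shape: tuple[int, int],
    microns_per_pixel: float,
    role: str = "epithelium",
) -> BinaryMask:
    """Rasterise a GeoJSON FeatureCollection of (Multi)Polygons to a mask.

    Coordinates are in pixel units of the target raster (x rightward,
    y downward).  A pixel (row, col) is inside iff the polygon covers its
    centre (col + 0.5, row + 0.5) — the half-open pixel-centre rule, so an
    axis-aligned rectangle (10,10)-(20,20) covers exactly 10x10 pixels.
    Interior rings (holes) are honoured; overlapping polygons are unioned.
    """
    import shapely
    from shapely.geometry import shape as shapely_shape

    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
    else:
        data = source
    feats = data.get("features", []) if data.get("type") == "FeatureCollection" else [data]
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    for i, feat in enumerate(feats):
        geom_dict = feat.get("geometry", feat)
        try:
            geom = shapely_shape(geom_dict)
            if not geom.is_valid:
                geom = geom.buffer(0)
        except Exception as exc:  # malformed coordinates / ring structure
            raise AnnotationError(f"polygon {i}: malformed geometry ({exc})") from exc
        if geom.is_empty:
            continue
        if geom.geom_type not in {"Polygon", "MultiPolygon"}:
            raise AnnotationError(f"polygon {i}: unsupported geometry {geom.geom_type}")
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(int(np.floor(minx - 1)), 0)
        c1 = min(int(np.ceil(maxx + 1)), w)
        r0 = max(int(np.floor(miny - 1)), 0)
        r1 = min(int(np.ceil(maxy + 1)), h)
        if c1 <= c0 or r1 <= r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = shapely.contains_xy(geom, cols.ravel() + 0.5, rows.ravel() + 0.5)
        out[r0:r1, c0:c1] |= inside.reshape(rows.shape)
    return BinaryMask(mask=out, microns_per_pixel=microns_per_pixel, role=role)
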