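"""Ground-truthed synthetic data: stained tissue tiles and cohort count tables.

Two generators make the whole pipeline testable without slide scans or a
patient cohort:

``generate_tissue_image``
    renders an H-DAB-stained colon-mucosa tile through the Beer-Lambert
    forward model (transmitted intensity ``I = 255 * 10^(-sum OD_s * v_s)``):
    crypt-like sinusoidal epithelial ribbons with a stronger hematoxylin
    wash, planted elliptical nuclei (hematoxylin in all, DAB added in
    stain-positive cells), and artefacts both below and above the nucleus
    area filter.  The returned ground truth records every planted cell with
    its class and compartment, the true masks, and the exact pre-quantisation
    stain OD maps.

``generate_cohort_counts``
    draws a per-biopsy count table with the statistical structure the
    mixed-model analysis assumes: log-normal counts with a subject random
    intercept (``count = round(exp(mu + b_subject + eps))``), planted group
    fold changes, a proximal/distal location effect, and an oral-steroid
    multiplier on gamma-delta counts.

Both are bit-reproducible under a fixed seed.  Geometry realism is
secondary to label correctness: crypt ribbons are sinusoidal bands, the
biopsy is a rectangle, and no attempt is made at photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .compartments import (
    LABEL_NAMES,
    CompartmentMaps,
    build_compartments,
    expand_epithelium,
)
from .staining import (
    STAIN_DAB,
    STAIN_HEMATOXYLIN,
    BinaryMask,
    CalibratedImage,
)

__all__ = [
    "SyntheticTissueSpec",
    "SyntheticGroundTruth",
    "GroupSpec",
    "CohortDesign",
    "InvalidSpecError",
    "InvalidDesignError",
    "STAINS",
    "COMPARTMENTS",
    "generate_tissue_image",
    "generate_cohort_counts",
    "default_cohort_design",
    "ibd_pattern_fold_changes",
]

STAINS = ("CD3", "TCRdelta")
COMPARTMENTS = ("epithelium", "subepithelial_band", "lamina_propria")


class InvalidSpecError(ValueError):
    """Tissue spec violates its invariants."""


class InvalidDesignError(ValueError):
    """Cohort design violates its invariants."""


# ---------------------------------------------------------------------------
# Tissue tile generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTissueSpec:
    """Parameters of one synthetic mucosa tile.

    Densities are cells per mm^2 of the compartment; OD levels are optical
    densities on the unit-vector stain scale.  Default OD levels are kept
    below the point where 8-bit quantisation of the rendered image would
    push the deconvolution round-trip error above 0.01 OD.
    """

    shape: tuple[int, int] = (512, 512)
    microns_per_pixel: float = 0.5
    n_crypts: int = 3
    crypt_halfwidth_um: float = 14.0
    crypt_amplitude_um: float = 10.0
    crypt_period_um: float = 130.0
    tissue_margin_um: float = 8.0
    cell_density: dict = field(default_factory=lambda: {
        "epithelium": 4000.0, "subepithelial_band": 3000.0, "lamina_propria": 3000.0})
    positive_fraction: dict = field(default_factory=lambda: {
        "epithelium": 0.06, "subepithelial_band": 0.12, "lamina_propria": 0.18})
    nucleus_radius_um: tuple[float, float] = (2.3, 3.8)
    min_separation_um: float = 7.5
    artefact_density: float = 80.0
    hematoxylin_od: float = 0.55
    dab_od: float = 0.45
    tissue_wash_od: float = 0.06
    epithelium_wash_od: float = 0.16
    speck_od: float = 0.9
    smear_od: float = 0.35
    edge_blur_um: float = 0.5
    noise: float = 0.004
    band_um: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 2 or min(self.shape) <= 0:
            raise InvalidSpecError("image shape must be positive (H, W)")
        if not self.microns_per_pixel > 0:
            raise InvalidSpecError("microns_per_pixel must be > 0")
        if any(v < 0 for v in self.cell_density.values()):
            raise InvalidSpecError("cell densities must be >= 0")
        if any(not 0 <= v <= 1 for v in self.positive_fraction.values()):
            raise InvalidSpecError("positive fractions must lie in [0, 1]")
        if not 0 < self.nucleus_radius_um[0] <= self.nucleus_radius_um[1]:
            raise InvalidSpecError("nucleus radii must be positive and ordered")
        if self.artefact_density < 0:
            raise InvalidSpecError("artefact density must be >= 0")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows about a rendered tile.

    ``cells`` has one row per planted object: centroid (x, y in px),
    nucleus_area_um2, cell_class in {positive, negative, artefact} and the
    compartment of the centroid under the centroid rule.  The float OD maps
    are the exact rendered (pre-quantisation) stain concentrations.
    """

    cells: pd.DataFrame
    tissue_mask: BinaryMask
    epithelium_mask: BinaryMask
    compartments: CompartmentMaps
    hematoxylin_od: np.ndarray
    dab_od: np.ndarray

    def save(self, directory: str | Path, stem: str = "truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / f"{stem}_cells.csv", index=False)
        self.tissue_mask.save(directory / f"{stem}_tissue.png")
        self.epithelium_mask.save(directory / f"{stem}_epithelium.png")
        self.compartments.save(directory / f"{stem}_compartments.png")


def _crypt_ribbons(spec: SyntheticTissueSpec, rng: np.random.Generator,
                   tissue: np.ndarray) -> np.ndarray:
    """Sinusoidal epithelial ribbons, vertically spaced, clipped to tissue."""
    h, w = spec.shape
    mpp = spec.microns_per_pixel
    halfwidth = spec.crypt_halfwidth_um / mpp
    amp = spec.crypt_amplitude_um / mpp
    period = spec.crypt_period_um / mpp
    margin = spec.tissue_margin_um / mpp
    mask = np.zeros(spec.shape, dtype=bool)
    if spec.n_crypts <= 0:
        return mask
    x = np.arange(w)
    # even vertical spacing, keeping the full swing inside the tissue
    pad = margin + amp + halfwidth + 2
    centres = np.linspace(pad, h - 1 - pad, spec.n_crypts)
    yy = np.arange(h)[:, None]
    for yc in centres:
        phase = rng.uniform(0, 2 * np.pi)
        centreline = yc + amp * np.sin(2 * np.pi * x / period + phase)
        mask |= np.abs(yy - centreline[None, :]) <= halfwidth
    return mask & tissue


def _sample_positions(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    exclusion_um: float,
    mpp: float,
    taken_xy: list[tuple[float, float]],
    taken_r: list[float],
    own_radius_um: float = 0.0,
) -> list[tuple[int, int]]:
    """Rejection-sample ``n`` pixel positions inside ``allowed`` keeping a
    pairwise physical exclusion distance to everything already placed."""
    ys, xs = np.nonzero(allowed)
    if ys.size == 0 or n <= 0:
        return []
    out: list[tuple[int, int]] = []
    max_tries = 60 * n + 200
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        k = rng.integers(ys.size)
        x, y = int(xs[k]), int(ys[k])
        if taken_xy:
            arr = np.asarray(taken_xy)
            rr = (np.asarray(taken_r) + exclusion_um / 2 + own_radius_um) / mpp
            d2 = (arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2
            if np.any(d2 < rr**2):
                continue
        out.append((x, y))
        taken_xy.append((x, y))
        taken_r.append(exclusion_um / 2 + own_radius_um)
    return out


def _paint_ellipse(canvas: np.ndarray, x: float, y: float, a_px: float,
                   b_px: float, theta: float, value: float) -> None:
    """Add ``value`` inside an ellipse (semi-axes in px) via np.maximum of the
    painted layer, so overlapping paint does not stack."""
    h, w = canvas.shape
    r = int(np.ceil(max(a_px, b_px))) + 1
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x1 <= x0 or y1 <= y0:
        return
    xs, ys = np.meshgrid(np.arange(x0, x1) - x, np.arange(y0, y1) - y)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xs * ct + ys * st) / a_px
    v = (-xs * st + ys * ct) / b_px
    inside = u * u + v * v <= 1.0
    region = canvas[y0:y1, x0:x1]
    region[inside] = np.maximum(region[inside], value)


def generate_tissue_image(
    spec: SyntheticTissueSpec,
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Render one synthetic H-DAB mucosa tile with full ground truth.

    Identical specs (same seed) give bit-identical images and truth tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    mpp = spec.microns_per_pixel
    px_area_mm2 = (mpp / 1000.0) ** 2

    margin = int(round(spec.tissue_margin_um / mpp))
    tissue = np.zeros(spec.shape, dtype=bool)
    tissue[margin:h - margin, margin:w - margin] = True

    epi = _crypt_ribbons(spec, rng, tissue)
    tissue_mask = BinaryMask(tissue, mpp, role="tissue")
    epi_mask = BinaryMask(epi, mpp, role="epithelium")
    expanded = expand_epithelium(epi_mask, spec.band_um)
    comps = build_compartments(tissue_mask, epi_mask, expanded)

    h_od = np.zeros(spec.shape)
    d_od = np.zeros(spec.shape)
    h_od[tissue] = spec.tissue_wash_od
    h_od[epi] = spec.epithelium_wash_od

    taken_xy: list[tuple[float, float]] = []
    taken_r: list[float] = []
    records: list[dict] = []

    for comp in COMPARTMENTS:
        allowed = comps.mask(comp)
        # keep nucleus centres clear of the image border
        allowed = allowed.copy()
        b = int(np.ceil(spec.nucleus_radius_um[1] / mpp)) + 2
        allowed[:b, :] = allowed[-b:, :] = False
        allowed[:, :b] = allowed[:, -b:] = False
        # count contract: density x full compartment label area
        area = comps.areas_mm2[comp]
        n_cells = int(round(spec.cell_density.get(comp, 0.0) * area))
        n_pos = int(round(spec.positive_fraction.get(comp, 0.0) * n_cells))
        pts = _sample_positions(rng, allowed, n_cells, spec.min_separation_um,
                                mpp, taken_xy, taken_r)
        for i, (x, y) in enumerate(pts):
            r_um = rng.uniform(*spec.nucleus_radius_um)
            ecc = rng.uniform(0.0, 0.15)
            a_um, b_um = r_um * (1 + ecc), r_um / (1 + ecc)
            theta = rng.uniform(0, np.pi)
            is_pos = i < n_pos
            _paint_ellipse(h_od, x, y, a_um / mpp, b_um / mpp, theta,
                           spec.epithelium_wash_od + spec.hematoxylin_od
                           if comp == "epithelium"
                           else spec.tissue_wash_od + spec.hematoxylin_od)
            if is_pos:
                _paint_ellipse(d_od, x, y, a_um / mpp, b_um / mpp, theta, spec.dab_od)
            records.append({
                "x": x, "y": y,
                "nucleus_area_um2": float(np.pi * a_um * b_um),
                "cell_class": "positive" if is_pos else "negative",
                "compartment": comp,
            })

    # Artefacts: half small high-OD specks (below the nucleus area filter),
    # half large smears (above it); both placed in tissue.
    tissue_area = tissue.sum() * px_area_mm2
    n_art = int(round(spec.artefact_density * tissue_area))
    n_speck = n_art // 2
    inner = tissue.copy()
    b = int(np.ceil(12.0 / mpp)) + 2
    inner[:b, :] = inner[-b:, :] = False
    inner[:, :b] = inner[:, -b:] = False
    for j in range(n_art):
        is_speck = j < n_speck
        radius_um = rng.uniform(0.5, 0.9) if is_speck else rng.uniform(8.0, 11.0)
        pts = _sample_positions(rng, inner, 1, spec.min_separation_um, mpp,
                                taken_xy, taken_r, own_radius_um=radius_um)
        if not pts:
            continue
        x, y = pts[0]
        theta = rng.uniform(0, np.pi)
        if is_speck:
            _paint_ellipse(h_od, x, y, radius_um / mpp, radius_um / mpp, theta,
                           spec.speck_od)
        else:
            _paint_ellipse(h_od, x, y, radius_um / mpp, 0.75 * radius_um / mpp,
                           theta, spec.tissue_wash_od + spec.smear_od)
            _paint_ellipse(d_od, x, y, radius_um / mpp, 0.75 * radius_um / mpp,
                           theta, 0.4 * spec.smear_od)
        records.append({
            "x": x, "y": y,
            "nucleus_area_um2": float(np.pi * radius_um * (radius_um if is_speck
                                                           else 0.75 * radius_um)),
            "cell_class": "artefact",
            "compartment": LABEL_NAMES[int(comps.labels[y, x])],
        })

    blur_px = spec.edge_blur_um / mpp
    if blur_px > 0:
        h_od = ndimage.gaussian_filter(h_od, blur_px)
        d_od = ndimage.gaussian_filter(d_od, blur_px)

    channel_od = h_od[..., None] * STAIN_HEMATOXYLIN + d_od[..., None] * STAIN_DAB
    intensity = 255.0 * np.power(10.0, -channel_od)
    if spec.noise > 0:
        intensity = intensity + rng.normal(0.0, spec.noise * 255.0, intensity.shape)
    rgb = np.clip(np.round(intensity), 0, 255).astype(np.uint8)

    cells = pd.DataFrame.from_records(
        records, columns=["x", "y", "nucleus_area_um2", "cell_class", "compartment"])
    image = CalibratedImage(rgb=rgb, microns_per_pixel=mpp,
                            ident=f"synthetic-seed{spec.seed}")
    truth = SyntheticGroundTruth(
        cells=cells, tissue_mask=tissue_mask, epithelium_mask=epi_mask,
        compartments=comps, hematoxylin_od=h_od, dab_od=d_od)
    return image, truth


# ---------------------------------------------------------------------------
# Cohort count generator
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One study group: name, size, diagnosis and histological activity."""

    name: str
    n_subjects: int
    diagnosis: str  # HC | UC | CD
    active: bool

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidDesignError(f"group {self.name}: n_subjects must be >= 1")


def ibd_pattern_fold_changes() -> dict:
    """Planted group fold changes (vs the healthy-control baseline) that
    mirror the qualitative compartment pattern of colonic IBD: more CD3 in
    the subepithelium/lamina propria with Crohn's and with activity, stable
    intraepithelial CD3, fewer gamma-delta IELs in inactive Crohn's than
    inactive UC, loss of gamma-delta IELs in active UC but not active
    Crohn's, and stable gamma-delta numbers below the epithelium."""
    fc = {
        "HC": {},
        "CD_inactive": {("CD3", "epithelium"): 1.4,
                        ("CD3", "subepithelial_band"): 1.6,
                        ("CD3", "lamina_propria"): 1.5,
                        ("TCRdelta", "epithelium"): 0.7},
        "UC_inactive": {("CD3", "epithelium"): 1.2,
                        ("CD3", "subepithelial_band"): 1.2,
                        ("CD3", "lamina_propria"): 1.2,
                        ("TCRdelta", "epithelium"): 1.4},
        "CD_active": {("CD3", "epithelium"): 1.4,
                      ("CD3", "subepithelial_band"): 2.3,
                      ("CD3", "lamina_propria"): 2.7,
                      ("TCRdelta", "epithelium"): 0.7},
        "UC_active": {("CD3", "epithelium"): 1.2,
                      ("CD3", "subepithelial_band"): 1.8,
                      ("CD3", "lamina_propria"): 2.3,
                      ("TCRdelta", "epithelium"): 0.4},
    }
    return fc


@dataclass
class CohortDesign:
    """Design of a synthetic cohort count table.

    ``baselines`` are geometric-mean counts per biopsy for the reference
    (first) group; ``fold_changes[group][(stain, compartment)]`` multiplies
    them on the natural-log scale (missing entries mean fold change 1).
    ``sigma_subject`` / ``sigma_resid`` are the between-subject and residual
    SDs of log counts.  Oral corticosteroid use multiplies gamma-delta
    counts by ``steroid_gd_multiplier``.
    """

    groups: list = field(default_factory=lambda: [
        GroupSpec("HC", 41, "HC", False),
        GroupSpec("UC_inactive", 39, "UC", False),
        GroupSpec("CD_inactive", 35, "CD", False),
        GroupSpec("UC_active", 44, "UC", True),
        GroupSpec("CD_active", 22, "CD", True),
    ])
    biopsies_per_subject: int = 2
    locations: tuple[str, ...] = ("proximal", "distal")
    baselines: dict = field(default_factory=lambda: {
        ("CD3", "epithelium"): 56.0,        # 2.8 per 100 of ~2000 epithelial cells
        ("CD3", "subepithelial_band"): 80.0,
        ("CD3", "lamina_propria"): 1050.0,  # ~700 per mm^2 over 1.5 mm^2
        ("TCRdelta", "epithelium"): 12.0,   # 0.6 per 100 epithelial cells
        ("TCRdelta", "subepithelial_band"): 7.0,
        ("TCRdelta", "lamina_propria"): 75.0,
    })
    fold_changes: dict = field(default_factory=ibd_pattern_fold_changes)
    sigma_subject: float = 0.5
    sigma_resid: float = 0.5
    proximal_fold_change: float = 1.3
    epithelial_cells_per_biopsy: float = 2000.0
    area_mm2_per_biopsy: float = 1.5
    denominator_sd: float = 0.05
    steroid_gd_multiplier: float = 0.6
    steroid_prob: dict = field(default_factory=lambda: {
        "HC": 0.0, "inactive": 0.10, "active": 0.25})
    blood_ratio_median: float = 2.9
    blood_ratio_sd_log: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise InvalidDesignError("cohort design needs at least one group")
        for g in self.groups:
            g.validate()
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise InvalidDesignError("log-scale SDs must be >= 0")
        for group_fc in self.fold_changes.values():
            if any(v <= 0 for v in group_fc.values()):
                raise InvalidDesignError("fold changes must be > 0")
        if self.biopsies_per_subject < 1:
            raise InvalidDesignError("biopsies_per_subject must be >= 1")


def default_cohort_design(**overrides) -> CohortDesign:
    """The study-condition cohort design (cohort-scale group sizes, planted
    qualitative pattern); keyword overrides replace individual fields."""
    return replace(CohortDesign(), **overrides) if overrides else CohortDesign()


def generate_cohort_counts(design: CohortDesign) -> pd.DataFrame:
    """Draw a cohort count table, one row per (subject, biopsy, stain,
    compartment).

    Counts are ``round(exp(mu + b_subject + eps))`` with ``mu`` the log
    baseline plus planted log fold changes and covariate effects,
    ``b_subject ~ N(0, sigma_subject^2)`` drawn per (subject, stain,
    compartment) and ``eps ~ N(0, sigma_resid^2)`` per row.  Counts are
    rounded, not truncated; zeros are allowed.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    for g in design.groups:
        p_ster = design.steroid_prob.get(
            g.diagnosis if g.diagnosis == "HC" else ("active" if g.active else "inactive"),
            0.0)
        for s in range(g.n_subjects):
            subject_id = f"{g.name}-{s:03d}"
            age = float(np.round(rng.normal(45.0, 13.0), 1))
            gender = "F" if rng.random() < 0.5 else "M"
            duration = 0.0 if g.diagnosis == "HC" else float(
                np.round(np.exp(rng.normal(np.log(60.0), 0.8)), 1))
            steroids = bool(rng.random() < p_ster)
            blood_ratio = float(np.round(
                design.blood_ratio_median * np.exp(
                    rng.normal(0.0, design.blood_ratio_sd_log)), 2))
            if g.active:
                nancy = int(rng.integers(2, 5))
            else:
                nancy = 0 if rng.random() < 0.7 else 1
            b_subj = {key: rng.normal(0.0, design.sigma_subject)
                      for key in design.baselines}
            for bi in range(design.biopsies_per_subject):
                location = design.locations[bi % len(design.locations)]
                for (stain, comp), base in design.baselines.items():
                    fc = design.fold_changes.get(g.name, {}).get((stain, comp), 1.0)
                    mu = np.log(base) + np.log(fc)
                    if location == "proximal":
                        mu += np.log(design.proximal_fold_change)
                    if steroids and stain == "TCRdelta":
                        mu += np.log(design.steroid_gd_multiplier)
                    eps = rng.normal(0.0, design.sigma_resid)
                    count = int(max(round(np.exp(mu + b_subj[(stain, comp)] + eps)), 0))
                    denom_noise = (rng.normal(0.0, design.denominator_sd)
                                   if design.denominator_sd > 0 else 0.0)
                    rows.append({
                        "subject_id": subject_id,
                        "group": g.name,
                        "diagnosis": g.diagnosis,
                        "nancy_grade": nancy,
                        "location": location,
                        "stain": stain,
                        "compartment": comp,
                        "count": count,
                        "epithelial_cells": int(round(
                            design.epithelial_cells_per_biopsy * np.exp(denom_noise))),
                        "area_mm2": float(np.round(
                            design.area_mm2_per_biopsy * np.exp(denom_noise), 4)),
                        "age": age,
                        "gender": gender,
                        "duration_months": duration,
                        "oral_steroids": steroids,
                        "blood_gd_cd3_ratio": blood_ratio,
                    })
    return pd.DataFrame(rows)
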