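"""Shared fixtures: synthetic tiles, matched detections, trained models."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mucoquant.cells import (
    detect_nuclei,
    expand_cells,
    filter_by_area,
    train_cell_classifier,
)
from mucoquant.staining import SegmenterSettings, separate_stains, train_epithelium_segmenter
from mucoquant.synthetic import SyntheticTissueSpec, generate_tissue_image


def match_to_truth(detections, truth_cells, tol_px=2.0):
    """One-to-one nearest assignment of detections to planted cells.

    Returns (pairs, n_unmatched_truth, n_unmatched_det) where pairs is a
    list of (detection, truth_row) with centroid distance <= tol_px.
    """
    tx = truth_cells[["x", "y"]].to_numpy(float)
    if len(detections) == 0 or len(tx) == 0:
        return [], len(tx), len(detections)
    dx = np.array([d.centroid for d in detections])
    dist = np.linalg.norm(tx[:, None, :] - dx[None, :, :], axis=2)
    cost = np.where(dist <= tol_px, dist, 1e9)
    ri, ci = linear_sum_assignment(cost)
    pairs = [(detections[c], truth_cells.iloc[r])
             for r, c in zip(ri, ci) if cost[r, c] <= tol_px]
    return pairs, len(tx) - len(pairs), len(detections) - len(pairs)


def pipeline_detections(image, truth=None, settings=None):
    """Stains -> detect -> area filter -> expand, on one tile."""
    stains = separate_stains(image)
    dets = detect_nuclei(stains, settings)
    dets = filter_by_area(dets, settings)
    dets = expand_cells(dets, stains, settings)
    return dets, stains


@pytest.fixture(scope="session")
def default_tile():
    return generate_tissue_image(SyntheticTissueSpec(seed=0))


@pytest.fixture(scope="session")
def default_detections(default_tile):
    image, truth = default_tile
    dets, stains = pipeline_detections(image)
    return dets, stains, truth


@pytest.fixture(scope="session")
def trained_classifier():
    """Three-class classifier trained on ground-truth-labelled detections
    from two tiles with extra artefacts."""
    dets, labels = [], []
    for seed in (30, 31):
        spec = SyntheticTissueSpec(seed=seed, artefact_density=400.0)
        image, truth = generate_tissue_image(spec)
        cand, stains = pipeline_detections(image)
        pairs, _, _ = match_to_truth(cand, truth.cells, tol_px=6.0)
        for det, row in pairs:
            dets.append(det)
            labels.append(row.cell_class)
    return train_cell_classifier(dets, labels, seed=0)


@pytest.fixture(scope="session")
def trained_segmenter():
    """Epithelium segmenter trained on two tiles (held-out tiles elsewhere)."""
    tiles = [generate_tissue_image(SyntheticTissueSpec(seed=s)) for s in (10, 11)]
    settings = SegmenterSettings(seed=0, n_estimators=40, max_samples_per_image=25_000)
    return train_epithelium_segmenter(
        [t[0] for t in tiles], [t[1].epithelium_mask for t in tiles], settings)
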