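"""Dearraying: find spheroid spots on a slide scan and map them to the grid.

A microTMA slide carries up to 96 small (~350 µm) spheroid spots on a
regular grid. Spots are detected on the nuclear-channel scan by Gaussian
smoothing, Otsu thresholding and connected-component analysis, filtered by
equivalent diameter; detections are then assigned to the nearest expected
grid node within half a pitch, which partitions the slide plane
unambiguously. Missing spots are reported, not raised: a TMA section
routinely loses a few spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .types import MultiplexImage, TMALayout, um_to_px

logger = logging.getLogger(__name__)


@dataclass
class SpotDetection:
    """One candidate TMA spot found on the slide."""

    centroid: tuple[float, float]  # (x, y) pixels
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    area_px: int
    equivalent_diameter_um: float
    grid: tuple[int, int] | None = None
    treatment: str | None = None
    assigned: bool = False


def detect_spots(
    slide: MultiplexImage | np.ndarray,
    min_spot_diameter_um: float = 150.0,
    max_spot_diameter_um: float = 600.0,
    pixel_size_um: float | None = None,
    smooth_sigma_um: float | None = None,
) -> list[SpotDetection]:
    """Detect spheroid spots on a nuclear-channel slide scan.

    Pipeline: Gaussian smooth (sigma defaults to ``min_spot_diameter / 8``)
    -> Otsu threshold -> 8-connected components -> keep components whose
    equivalent diameter lies in ``[min, max]``. A blank slide yields an empty
    list with a warning log, not an error.
    """
    if isinstance(slide, MultiplexImage):
        img = slide.nuclear
        pixel_size_um = slide.pixel_size_um
    else:
        img = np.asarray(slide, dtype=float)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for a bare array slide")
    if img.ndim != 2:
        raise ValueError("slide must be a single 2D channel")
    if smooth_sigma_um is None:
        smooth_sigma_um = min_spot_diameter_um / 8.0

    smoothed = ndimage.gaussian_filter(
        np.asarray(img, dtype=np.float32), smooth_sigma_um / pixel_size_um
    )
    if np.ptp(smoothed) == 0:
        logger.warning("blank slide: no intensity variation, no spots detected")
        return []
    # cap at the 99th percentile so a small bright artifact (dust, debris)
    # cannot drag the threshold above the tissue level
    capped = np.minimum(smoothed, np.percentile(smoothed, 99))
    if np.ptp(capped) == 0:
        logger.warning("blank slide: no intensity variation, no spots detected")
        return []
    mask = smoothed > threshold_otsu(capped)
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))

    detections = []
    for prop in regionprops(labels):
        eq_d_um = prop.equivalent_diameter_area * pixel_size_um
        if not min_spot_diameter_um <= eq_d_um <= max_spot_diameter_um:
            continue
        r0, c0, r1, c1 = prop.bbox
        cy, cx = prop.centroid
        detections.append(
            SpotDetection(
                centroid=(float(cx), float(cy)),
                bbox=(int(c0), int(r0), int(c1), int(r1)),
                area_px=int(prop.area),
                equivalent_diameter_um=float(eq_d_um),
            )
        )
    if not detections:
        logger.warning("no spots within diameter bounds on this slide")
    detections.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
    return detections


def assign_grid(
    detections: list[SpotDetection],
    layout: TMALayout,
    pixel_size_um: float,
) -> tuple[list[SpotDetection], list[tuple[int, int]]]:
    """Assign detections to expected grid nodes; report missing spots.

    Each detection goes to its nearest occupied grid node if within half a
    pitch; when two detections contend for one node the nearer wins and the
    other stays unassigned. Assignment is injective by construction. Returns
    the (mutated) detections and the list of occupied nodes with no detection.
    """
    tol_px = layout.spot_pitch_um / 2.0 / pixel_size_um
    nodes = layout.occupied
    node_xy = np.array(
        [layout.node_center_um(r, c) for (r, c) in nodes], dtype=float
    ) / pixel_size_um

    # candidate (distance, detection, node) triples within tolerance
    cands = []
    for det in detections:
        det.grid = None
        det.treatment = None
        det.assigned = False
        if not nodes:
            continue
        d = np.hypot(*(node_xy - np.asarray(det.centroid)).T)
        i = int(np.argmin(d))
        if d[i] <= tol_px:
            cands.append((float(d[i]), det, nodes[i]))

    taken: dict[tuple[int, int], SpotDetection] = {}
    for dist, det, node in sorted(cands, key=lambda t: t[0]):
        if node in taken:
            continue  # a nearer detection already claimed this node
        taken[node] = det
        det.grid = node
        det.treatment = layout.treatment_map[node]
        det.assigned = True
    missing = [node for node in nodes if node not in taken]
    return detections, missing


def crop_spots(
    slide: MultiplexImage,
    detections: list[SpotDetection],
    pad_um: float = 0.0,
) -> list[MultiplexImage]:
    """Cut per-spot sub-images (assigned detections only), clipped at edges.

    Each crop carries its grid coordinate, treatment and source box in
    metadata so downstream per-cell tables keep their provenance.
    """
    crops = []
    h, w = slide.shape
    pad = um_to_px(pad_um, slide.pixel_size_um)
    for det in detections:
        if not det.assigned:
            continue
        x0, y0, x1, y1 = det.bbox
        x0, y0 = max(x0 - pad, 0), max(y0 - pad, 0)
        x1, y1 = min(x1 + pad, w), min(y1 + pad, h)
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"zero-area crop for spot {det.grid}: box {det.bbox}")
        crops.append(
            MultiplexImage(
                channels={k: v[y0:y1, x0:x1].copy() for k, v in slide.channels.items()},
                pixel_size_um=slide.pixel_size_um,
                metadata={
                    **slide.metadata,
                    "grid": det.grid,
                    "treatment": det.treatment,
                    "crop_box": (x0, y0, x1, y1),
                },
            )
        )
    return crops
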