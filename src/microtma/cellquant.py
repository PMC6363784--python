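"""Per-cell quantification of dual-IF spheroid sections.

The measurement follows the analysis used for glioblastoma BrainSphere
(gBS) microarrays: nuclei are located in the blue (Hoechst/DAPI) channel as
local maxima of a Difference-of-Gaussian (DoG) band-pass image; around each
nucleus centre the mean intensity within the cell radius (~10 µm) is measured
in the red (anti-GFP, tumor) and green (Ki67 or cleaved caspase-3) channels;
cells are classified tumor/normal by a red-channel threshold and marker
positive/negative by a green-channel threshold. Three per-spheroid endpoints
are reported:

1. tumor cells as a percentage of all cells,
2. marker-positive tumor cells as a percentage of tumor cells,
3. marker-positive normal cells as a percentage of normal cells.

Secondary variants with all cells as denominator are also reported, because
published dose–response panels are sometimes normalised either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .types import MultiplexImage, um_to_px


@dataclass
class DetectionParams:
    """Tunable parameters of nucleus detection and cell classification.

    ``cell_radius_um`` is the radius of the averaged cell area (~10 µm).
    DoG sigmas default to a band-pass matched to the nuclear-core scale:
    ``sigma_small = cell_radius / 4`` and ``sigma_large = 1.6 * sigma_small``.
    The band must sit at the nucleus, not the cell: in confluent tissue cell
    centres approach one nucleus radius, and a coarser band flattens the
    packed carpet into a ripple below any threshold.
    ``min_center_distance_um`` (default ``cell_radius / 2``) suppresses
    duplicate maxima of one nucleus without merging true neighbours.

    ``detection_threshold`` is a fraction of the DoG maximum when
    ``detection_threshold_mode == "relative"``, otherwise an absolute DoG
    response. Channel thresholds are ``"otsu"`` (computed on the distribution
    of per-cell mean intensities of the spheroid) or ``"fixed:<value>"``.
    """

    cell_radius_um: float = 10.0
    dog_sigma_small_um: float | None = None
    dog_sigma_large_um: float | None = None
    min_center_distance_um: float | None = None
    detection_threshold: float = 0.1
    detection_threshold_mode: str = "relative"
    red_threshold_mode: str = "otsu"
    green_threshold_mode: str = "otsu"

    def __post_init__(self) -> None:
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be > 0")
        if self.dog_sigma_small_um is None:
            self.dog_sigma_small_um = self.cell_radius_um / 4.0
        if self.dog_sigma_large_um is None:
            self.dog_sigma_large_um = 1.6 * self.dog_sigma_small_um
        if not self.dog_sigma_small_um < self.dog_sigma_large_um:
            raise ValueError("dog_sigma_small_um must be < dog_sigma_large_um")
        if self.min_center_distance_um is None:
            self.min_center_distance_um = self.cell_radius_um / 2.0
        if self.detection_threshold_mode not in ("relative", "absolute"):
            raise ValueError(
                "detection_threshold_mode must be 'relative' or 'absolute'"
            )


@dataclass
class CellRecord:
    """One detected cell: centre, per-channel disc means, and labels."""

    center: tuple[float, float]  # (x, y) pixels
    mean_nuclear: float
    mean_red: float
    mean_green: float
    compartment: str  # "tumor" | "normal"
    marker: str  # "positive" | "negative"


@dataclass
class SpheroidQuant:
    """Counts and percentage endpoints for one spheroid section.

    Percentages whose denominator is zero are ``None`` (reported missing,
    never coerced to 0). ``pct_marker_*_of_total`` are the secondary variants
    normalised to all cells instead of the compartment.
    """

    n_total: int
    n_tumor: int
    n_normal: int
    n_marker_tumor: int
    n_marker_normal: int
    pct_tumor: float | None
    pct_marker_tumor: float | None
    pct_marker_normal: float | None
    pct_marker_tumor_of_total: float | None = None
    pct_marker_normal_of_total: float | None = None


def _pct(num: int, denom: int) -> float | None:
    return 100.0 * num / denom if denom > 0 else None


def quantify_labels(
    compartments: Sequence[str], markers: Sequence[str]
) -> SpheroidQuant:
    """Endpoint arithmetic from parallel compartment / marker label lists."""
    if len(compartments) != len(markers):
        raise ValueError("compartments and markers must have equal length")
    comp = np.asarray(compartments, dtype=object)
    mark = np.asarray(markers, dtype=object)
    n_total = len(comp)
    tumor = comp == "tumor"
    pos = mark == "positive"
    n_tumor = int(tumor.sum())
    n_normal = n_total - n_tumor
    n_mt = int((tumor & pos).sum())
    n_mn = int((~tumor & pos).sum())
    return SpheroidQuant(
        n_total=n_total,
        n_tumor=n_tumor,
        n_normal=n_normal,
        n_marker_tumor=n_mt,
        n_marker_normal=n_mn,
        pct_tumor=_pct(n_tumor, n_total),
        pct_marker_tumor=_pct(n_mt, n_tumor),
        pct_marker_normal=_pct(n_mn, n_normal),
        pct_marker_tumor_of_total=_pct(n_mt, n_total),
        pct_marker_normal_of_total=_pct(n_mn, n_total),
    )


def detect_nuclei(
    nuclear: np.ndarray,
    params: DetectionParams | None = None,
    pixel_size_um: float = 0.5,
) -> np.ndarray:
    """Locate nucleus centres in the nuclear-counterstain channel.

    The channel is band-pass filtered with a Difference of Gaussians
    (``G(sigma_small) - G(sigma_large)``); centres are strict local maxima of
    the response above the detection threshold, greedily kept in decreasing
    response order subject to a pairwise Euclidean separation of at least
    ``min_center_distance_um``.

    Returns an ``(n, 2)`` float array of ``(x, y)`` pixel coordinates in
    deterministic row-major (y, then x) order.
    """
    params = params or DetectionParams()
    nuclear = np.asarray(nuclear, dtype=np.float64)
    if nuclear.ndim != 2:
        raise ValueError(f"nuclear channel must be 2D, got {nuclear.ndim}D")

    s1 = params.dog_sigma_small_um / pixel_size_um
    s2 = params.dog_sigma_large_um / pixel_size_um
    dog = ndimage.gaussian_filter(nuclear, s1) - ndimage.gaussian_filter(nuclear, s2)

    peak = float(dog.max()) if dog.size else 0.0
    if params.detection_threshold_mode == "relative":
        if peak <= 0:
            return np.empty((0, 2))
        thr = params.detection_threshold * peak
    else:
        thr = params.detection_threshold
    # strict 8-neighbour maxima; spacing is enforced exactly below
    cand = peak_local_max(dog, min_distance=1, threshold_abs=thr, exclude_border=False)
    if len(cand) == 0:
        return np.empty((0, 2))

    order = np.argsort(dog[cand[:, 0], cand[:, 1]], kind="stable")[::-1]
    cand = cand[order].astype(float)
    min_d2 = (params.min_center_distance_um / pixel_size_um) ** 2
    kept = np.empty_like(cand)
    n_kept = 0
    for rc in cand:
        if n_kept and (((kept[:n_kept] - rc) ** 2).sum(axis=1) < min_d2).any():
            continue
        kept[n_kept] = rc
        n_kept += 1
    centers_rc = kept[:n_kept]
    # row-major output order: by row, then column
    order = np.lexsort((centers_rc[:, 1], centers_rc[:, 0]))
    centers_rc = centers_rc[order]
    return centers_rc[:, ::-1].copy()  # (x, y)


def _disc_offsets(radius_px: int) -> np.ndarray:
    """Integer (dr, dc) offsets of the pixel disc of given radius."""
    r = np.arange(-radius_px, radius_px + 1)
    dr, dc = np.meshgrid(r, r, indexing="ij")
    inside = dr**2 + dc**2 <= radius_px**2
    return np.stack([dr[inside], dc[inside]], axis=1)


def _disc_mean(channel: np.ndarray, cx: float, cy: float, offsets: np.ndarray) -> float:
    rows = int(round(cy)) + offsets[:, 0]
    cols = int(round(cx)) + offsets[:, 1]
    ok = (rows >= 0) & (rows < channel.shape[0]) & (cols >= 0) & (cols < channel.shape[1])
    return float(channel[rows[ok], cols[ok]].mean())


def _resolve_threshold(mode: str, values: np.ndarray) -> float:
    """Parse 'fixed:<v>' or compute Otsu on the per-cell mean distribution."""
    if mode.startswith("fixed:"):
        return float(mode.split(":", 1)[1])
    if mode == "otsu":
        from skimage.filters import threshold_otsu

        if values.size == 0:
            return 0.0
        if np.ptp(values) == 0:
            # degenerate: one mode only; ties are negative, so nothing passes
            return float(values[0])
        return float(threshold_otsu(values))
    raise ValueError(f"unknown threshold mode {mode!r} (use 'otsu' or 'fixed:<value>')")


def classify_cells(
    image: MultiplexImage,
    centers: np.ndarray | Iterable[tuple[float, float]],
    params: DetectionParams | None = None,
) -> list[CellRecord]:
    """Measure disc means around each centre and assign compartment/marker.

    The mean is taken over the disc of ``cell_radius_um`` clipped to the
    image bounds (edge cells keep their in-bounds pixels). A cell is tumor if
    its red mean is strictly above the red threshold, and marker-positive if
    its green mean is strictly above the green threshold; ties are negative.
    """
    params = params or DetectionParams()
    centers = np.asarray(list(centers) if not isinstance(centers, np.ndarray) else centers, dtype=float)
    if centers.size == 0:
        return []
    centers = centers.reshape(-1, 2)

    r_px = um_to_px(params.cell_radius_um, image.pixel_size_um)
    offsets = _disc_offsets(r_px)
    means = {
        name: np.array([_disc_mean(ch, cx, cy, offsets) for cx, cy in centers])
        for name, ch in (("nuclear", image.nuclear), ("red", image.red), ("green", image.green))
    }
    red_thr = _resolve_threshold(params.red_threshold_mode, means["red"])
    green_thr = _resolve_threshold(params.green_threshold_mode, means["green"])

    records = []
    for i, (cx, cy) in enumerate(centers):
        records.append(
            CellRecord(
                center=(float(cx), float(cy)),
                mean_nuclear=means["nuclear"][i],
                mean_red=means["red"][i],
                mean_green=means["green"][i],
                compartment="tumor" if means["red"][i] > red_thr else "normal",
                marker="positive" if means["green"][i] > green_thr else "negative",
            )
        )
    return records


def quantify_spheroid(records: Sequence[CellRecord]) -> SpheroidQuant:
    """Aggregate cell records into per-spheroid counts and percentages."""
    return quantify_labels(
        [r.compartment for r in records], [r.marker for r in records]
    )
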