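"""Seeded synthetic gBS spheroid sections, microTMA slides and plates.

The generator emulates the statistical structure of dual-IF stained
glioblastoma BrainSphere (gBS) sections: a ~350 µm disc of contact-packed
cells, GFP-positive tumor cells clustered into a few compact foci inside a
GFP-negative neural background, per-compartment marker-positive fractions
(Ki67 or cleaved caspase-3), and additive imaging noise. Every image comes
with full ground truth (cell centres and true labels), so detection and
classification can be scored exactly.

Cell centres are laid on a randomly rotated, jittered hexagonal lattice
whose spacing adapts to the requested cell number. This reaches the
near-confluent densities of real spheroid sections (which random dart
throwing cannot) while guaranteeing a minimum centre separation of one
nucleus radius. Label allocation is deterministic (``round``, then assign by
proximity to tumor foci), so ground-truth fractions are exact.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellquant import SpheroidQuant, quantify_labels
from .spectral import EndmemberMatrix, SpectralStack
from .stats import ViabilityPlate
from .types import MultiplexImage, TMALayout, um_to_px


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class IntensityLevels:
    """Per-channel rendering amplitudes (arbitrary fluorescence units).

    ``background`` is the constant offset of every channel; the other fields
    are peak amplitudes of the per-cell Gaussian stamps above background.
    """

    background: float = 10.0
    nuclear: float = 200.0
    red: float = 200.0
    green: float = 200.0


@dataclass
class SectionParams:
    """Parameters of one synthetic spheroid section.

    Defaults reflect the gBS system: a disc of ~350 µm diameter imaged at
    0.5 µm/px (typical 20x scan), cells of ~10 µm radius, roughly half
    tumor. Marker fractions are the per-compartment proportions of
    marker-positive cells and are realised exactly (rounded to counts).
    """

    spheroid_diameter_um: float = 350.0
    pixel_size_um: float = 0.5
    n_cells: int = 400
    tumor_fraction: float = 0.5
    marker_frac_tumor: float = 0.3
    marker_frac_normal: float = 0.05
    nucleus_radius_um: float = 10.0
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    noise_sd: float = 10.0
    seed: int = 0
    n_tumor_foci: int | None = None  # None: drawn uniformly from {1, 2, 3}
    margin_um: float = 50.0

    def __post_init__(self) -> None:
        for name in ("tumor_fraction", "marker_frac_tumor", "marker_frac_normal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spheroid_diameter_um <= 0 or self.nucleus_radius_um <= 0:
            raise ValueError("diameters and radii must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_tumor_foci is not None and not 1 <= self.n_tumor_foci:
            raise ValueError("n_tumor_foci must be >= 1")


@dataclass
class GroundTruth:
    """True cell placements and labels of one synthetic section.

    ``cells`` has one row per cell with columns ``x``, ``y`` (pixel
    coordinates in the section image), ``compartment`` and ``marker``.
    """

    cells: pd.DataFrame
    disc_center_px: tuple[float, float]
    disc_radius_px: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def true_quant(self) -> SpheroidQuant:
        """Counts and percentage endpoints recomputed from the true labels."""
        return quantify_labels(
            list(self.cells["compartment"]), list(self.cells["marker"])
        )


# ---------------------------------------------------------------------------
# cell placement


def _hex_sites(
    spacing: float, radius: float, theta: float, frac: np.ndarray
) -> np.ndarray:
    """Hexagonal lattice points (x, y) within a disc of given radius at 0."""
    if radius <= 0:
        return np.empty((0, 2))
    dy = spacing * math.sqrt(3.0) / 2.0
    extent = radius + 2 * spacing
    nrow = int(extent / dy) + 1
    ncol = int(extent / spacing) + 1
    pts = []
    for j in range(-nrow, nrow + 1):
        xoff = (j % 2) * spacing / 2.0 + frac[0] * spacing
        y = j * dy + frac[1] * spacing
        xs = np.arange(-ncol, ncol + 1) * spacing + xoff
        pts.append(np.stack([xs, np.full_like(xs, y)], axis=1))
    pts = np.concatenate(pts)
    c, s = math.cos(theta), math.sin(theta)
    pts = pts @ np.array([[c, -s], [s, c]]).T
    return pts[(pts**2).sum(axis=1) <= radius**2]


def _place_centers(
    rng: np.random.Generator, n: int, disc_radius_px: float, min_dist_px: float
) -> np.ndarray:
    """Place ``n`` centres in a disc with pairwise separation >= min_dist_px."""
    if n == 0:
        return np.empty((0, 2))
    theta = rng.uniform(0, math.pi / 3)
    frac = rng.random(2)

    def jitter_radius(s: float) -> float:
        return 0.45 * (s - min_dist_px)

    def count(s: float) -> int:
        return len(_hex_sites(s, disc_radius_px - jitter_radius(s), theta, frac))

    lo, hi = min_dist_px, min_dist_px + 2 * disc_radius_px
    if count(lo) < n:
        raise ValueError(
            f"n_cells={n} exceeds packing capacity ({count(lo)} centres at "
            f"minimum spacing {min_dist_px:.1f} px in a disc of radius "
            f"{disc_radius_px:.1f} px)"
        )
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if count(mid) >= n:
            lo = mid
        else:
            hi = mid
    # the bisection invariant keeps count(lo) >= n; fall back to the minimum
    # spacing (verified above) if numerical drift ever broke it
    spacing = lo if count(lo) >= n else min_dist_px
    j = jitter_radius(spacing)
    sites = _hex_sites(spacing, disc_radius_px - j, theta, frac)
    chosen = sites[rng.choice(len(sites), size=n, replace=False)]
    ang = rng.uniform(0, 2 * math.pi, n)
    rad = j * np.sqrt(rng.random(n))
    return chosen + np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)


def _allocate_labels(
    rng: np.random.Generator, centers: np.ndarray, params: SectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically assign tumor/normal and marker labels.

    Tumor labels go to the ``round(tumor_fraction * n)`` cells nearest (by
    minimum distance) to 1-3 seeded focus centres, producing compact
    contiguous foci. Marker-positive labels are assigned per compartment to
    hit ``round(frac * compartment size)`` exactly, as compact clusters
    around a seeded point of the compartment: proliferation and apoptosis
    are regional in tissue, not independent per cell.
    """
    n = len(centers)
    compartment = np.array(["normal"] * n, dtype=object)
    marker = np.array(["negative"] * n, dtype=object)
    n_tumor = _round_half_up(params.tumor_fraction * n)
    if n_tumor > 0:
        n_foci = params.n_tumor_foci or int(rng.integers(1, 4))
        r = (centers**2).sum(axis=1) ** 0.5
        rmax = max(r.max(), 1.0)
        ang = rng.uniform(0, 2 * math.pi, n_foci)
        frad = rng.uniform(0, 0.5 * rmax, n_foci)
        foci = np.stack([frad * np.cos(ang), frad * np.sin(ang)], axis=1)
        d = np.min(
            np.linalg.norm(centers[:, None, :] - foci[None, :, :], axis=2), axis=1
        )
        tumor_idx = np.argsort(d, kind="stable")[:n_tumor]
        compartment[tumor_idx] = "tumor"
    for comp, frac in (("tumor", params.marker_frac_tumor),
                       ("normal", params.marker_frac_normal)):
        idx = np.flatnonzero(compartment == comp)
        k = _round_half_up(frac * len(idx))
        if k > 0:
            anchor = centers[rng.choice(idx)]
            d = np.linalg.norm(centers[idx] - anchor, axis=1)
            marker[idx[np.argsort(d, kind="stable")[:k]]] = "positive"
    return compartment, marker


# ---------------------------------------------------------------------------
# rendering


def _stamp_gaussians(
    img: np.ndarray, centers: np.ndarray, sigma_px: float, amplitude: float
) -> None:
    """Add a Gaussian of given peak amplitude at each (x, y) centre, in place."""
    if len(centers) == 0:
        return
    h, w = img.shape
    half = int(math.ceil(4 * sigma_px))
    for cx, cy in centers:
        r0 = max(int(math.floor(cy)) - half, 0)
        r1 = min(int(math.floor(cy)) + half + 1, h)
        c0 = max(int(math.floor(cx)) - half, 0)
        c1 = min(int(math.floor(cx)) + half + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1, dtype=np.float64)[:, None] - cy
        xx = np.arange(c0, c1, dtype=np.float64)[None, :] - cx
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -(yy**2 + xx**2) / (2.0 * sigma_px**2)
        )


def _render_section(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    centers_xy: np.ndarray,
    compartment: np.ndarray,
    marker: np.ndarray,
    params: SectionParams,
) -> dict[str, np.ndarray]:
    """Noise-free channel images for given absolute cell centres."""
    lv = params.intensity_levels
    r_nuc_px = params.nucleus_radius_um / params.pixel_size_um
    sigma_nuc = r_nuc_px / 4.0  # Hoechst stains the compact nucleus, not the cell
    sigma_cyto = r_nuc_px / 2.0  # cytoplasmic stains fill more of the cell
    chans = {name: np.zeros(shape, dtype=np.float64) for name in ("nuclear", "red", "green")}
    _stamp_gaussians(chans["nuclear"], centers_xy, sigma_nuc, lv.nuclear)
    _stamp_gaussians(chans["red"], centers_xy[compartment == "tumor"], sigma_cyto, lv.red)
    _stamp_gaussians(chans["green"], centers_xy[marker == "positive"], sigma_cyto, lv.green)
    return chans


def generate_section(params: SectionParams) -> tuple[MultiplexImage, GroundTruth]:
    """Render one dual-IF spheroid section with exact ground truth.

    Returns the three-channel image (nuclear, red, green) and the true cell
    table. Identical ``params`` (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    side = um_to_px(params.spheroid_diameter_um + 2 * params.margin_um, px)
    c0 = (side - 1) / 2.0
    disc_r_px = params.spheroid_diameter_um / (2.0 * px)
    min_dist_px = params.nucleus_radius_um / px

    rel = _place_centers(rng, params.n_cells, disc_r_px, min_dist_px)
    centers = rel + c0
    compartment, marker = _allocate_labels(rng, rel, params)

    chans = _render_section((side, side), (c0, c0), centers, compartment, marker, params)
    lv = params.intensity_levels
    for name in ("nuclear", "red", "green"):
        ch = chans[name] + lv.background
        ch += rng.normal(0.0, params.noise_sd, ch.shape)
        chans[name] = np.clip(ch, 0.0, None).astype(np.float32)

    cells = pd.DataFrame(
        {
            "x": centers[:, 0],
            "y": centers[:, 1],
            "compartment": compartment,
            "marker": marker,
        }
    )
    image = MultiplexImage(
        channels=chans,
        pixel_size_um=px,
        metadata={"seed": params.seed, "kind": "synthetic_section"},
    )
    truth = GroundTruth(cells=cells, disc_center_px=(c0, c0), disc_radius_px=disc_r_px)
    return image, truth


# ---------------------------------------------------------------------------
# whole-slide microTMA


def generate_tma_slide(
    layout: TMALayout,
    params: SectionParams,
    per_treatment: dict[str, SectionParams] | None = None,
    seed: int = 0,
) -> tuple[
    MultiplexImage,
    dict[tuple[int, int], GroundTruth],
    dict[tuple[int, int], tuple[int, int, int, int]],
]:
    """Render a whole microTMA slide of spheroid sections on a grid.

    Each occupied spot is a full section generated with a per-spot seed
    derived from ``seed`` and its grid coordinate, pasted centred on its grid
    node; unoccupied area is background plus noise. ``per_treatment`` maps a
    treatment label to the ``SectionParams`` used for its spots (dose-response
    effects are injected by varying ``n_cells``/``tumor_fraction``/marker
    fractions per arm); ``params`` is the fallback.

    Returns the slide image, per-spot ground truth (cell coordinates local to
    the spot's own section canvas), and per-spot bounding boxes
    ``(x0, y0, x1, y1)`` in slide pixels tight around the spheroid disc.
    """
    per_treatment = per_treatment or {}
    px = params.pixel_size_um
    pitch_px = layout.spot_pitch_um / px
    for p in [params, *per_treatment.values()]:
        if p.spheroid_diameter_um > layout.spot_pitch_um:
            raise ValueError(
                f"spot diameter {p.spheroid_diameter_um} um exceeds pitch "
                f"{layout.spot_pitch_um} um: spots would overlap"
            )
        if p.pixel_size_um != px:
            raise ValueError("all SectionParams on one slide must share pixel_size_um")

    w_um, h_um = layout.slide_size_um
    H, W = um_to_px(h_um, px), um_to_px(w_um, px)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
    lv = params.intensity_levels
    slide = {
        name: np.clip(
            lv.background + rng.normal(0.0, params.noise_sd, (H, W)), 0.0, None
        ).astype(np.float32)
        for name in ("nuclear", "red", "green")
    }

    truths: dict[tuple[int, int], GroundTruth] = {}
    boxes: dict[tuple[int, int], tuple[int, int, int, int]] = {}
    for (r, c) in layout.occupied:
        treatment = layout.treatment_map[(r, c)]
        base = per_treatment.get(treatment, params)
        # cap the margin so the pasted canvas stays inside the pitch cell
        margin = min(base.margin_um, (layout.spot_pitch_um - base.spheroid_diameter_um) / 2.0)
        spot_seed = int(
            np.random.SeedSequence([seed, r, c]).generate_state(1)[0] % (2**31)
        )
        spot_params = dataclasses.replace(base, seed=spot_seed, margin_um=margin)
        img, truth = generate_section(spot_params)
        side = img.shape[0]
        nx, ny = layout.node_center_um(r, c)
        ncx, ncy = nx / px, ny / px
        r0 = int(round(ncy - side / 2.0))
        c0 = int(round(ncx - side / 2.0))
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r0 + side, H), min(c0 + side, W)
        for name in slide:
            slide[name][rr0:rr1, cc0:cc1] = img.channels[name][
                rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0
            ]
        truths[(r, c)] = truth
        d_px = base.spheroid_diameter_um / px
        boxes[(r, c)] = (
            int(round(ncx - d_px / 2)),
            int(round(ncy - d_px / 2)),
            int(round(ncx + d_px / 2)),
            int(round(ncy + d_px / 2)),
        )
    image = MultiplexImage(
        channels=slide,
        pixel_size_um=px,
        metadata={"seed": seed, "kind": "synthetic_tma_slide"},
    )
    return image, truths, boxes


# ---------------------------------------------------------------------------
# multispectral forward model


def generate_spectral_stack(
    image: MultiplexImage,
    endmembers: EndmemberMatrix,
    af_abundance_map: np.ndarray | None = None,
) -> SpectralStack:
    """Mix fluorophore abundance images into a multispectral stack.

    The per-pixel spectrum is the exact linear forward model
    ``spectrum = E @ (abundances, af_abundance)``, where the image channels
    supply the non-autofluorescence abundances (matched positionally to the
    non-AF endmember columns) and ``af_abundance_map`` supplies the
    autofluorescence abundance (zero if omitted). Because the model is exact,
    noise-free unmixing has this generator as its oracle.
    """
    non_af = [i for i in range(endmembers.n_components) if i != endmembers.af_index]
    chans = list(image.channels.values())
    if len(chans) != len(non_af):
        raise ValueError(
            f"image has {len(chans)} channels but endmembers have "
            f"{len(non_af)} non-AF components"
        )
    h, w = image.shape
    abund = np.zeros((h, w, endmembers.n_components), dtype=np.float64)
    for col, ch in zip(non_af, chans):
        abund[:, :, col] = ch
    if af_abundance_map is not None:
        af_abundance_map = np.asarray(af_abundance_map, dtype=np.float64)
        if af_abundance_map.shape != (h, w):
            raise ValueError(
                f"af_abundance_map shape {af_abundance_map.shape} != image shape {(h, w)}"
            )
        if endmembers.af_index is None:
            if np.any(af_abundance_map):
                raise ValueError(
                    "af_abundance_map given but endmembers have no AF column"
                )
        else:
            abund[:, :, endmembers.af_index] = af_abundance_map
    data = np.einsum("hwc,bc->hwb", abund, endmembers.matrix)
    return SpectralStack(
        data=data,
        wavelengths=list(endmembers.wavelengths),
        pixel_size_um=image.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# resazurin viability plates


def generate_viability_plate(
    doses: list[str],
    relative_means: list[float],
    sd: float,
    n_replicates: int = 3,
    seed: int = 0,
    control: str | None = None,
) -> ViabilityPlate:
    """Simulate resazurin (resorufin fluorescence) replicate readings.

    Each dose group gets ``n_replicates`` values drawn from
    ``Normal(mean, sd)``. ``control`` defaults to the first dose label.
    """
    if len(doses) != len(relative_means):
        raise ValueError("doses and relative_means must have equal length")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    control = control if control is not None else doses[0]
    rng = np.random.default_rng(seed)
    values = {
        str(d): rng.normal(m, sd, n_replicates)
        for d, m in zip(doses, relative_means)
    }
    return ViabilityPlate(doses=[str(d) for d in doses], values=values, control=str(control))
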