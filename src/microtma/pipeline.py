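"""Pipeline orchestration: simulate -> [unmix] -> dearray -> quantify -> stats.

Two usage patterns mirror the two acquisition modes of a microTMA study:
*manual* single-spheroid quantification (one section image in, one row of
endpoints out) and *automated* slide mode (whole-slide scan in, dearrayed
per-spot endpoints and treatment statistics out). Every run writes a
manifest listing its artifacts with SHA-256 checksums, the full config and
the seed, so tabular outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import dearray as _dearray
from . import io as mio
from .cellquant import classify_cells, detect_nuclei, quantify_spheroid
from .spectral import EndmemberMatrix, default_endmembers, unmix
from .stats import boxplot_figure, compare_to_control, summarize, viability_analysis
from .synthetic import SectionParams, generate_spectral_stack, generate_tma_slide
from .types import MultiplexImage, TMALayout

logger = logging.getLogger(__name__)

ENDPOINTS = ("pct_tumor", "pct_marker_tumor", "pct_marker_normal")


def build_slide_plan(config: mio.RunConfig) -> tuple[TMALayout, SectionParams, dict]:
    """Layout and per-treatment section parameters from a run config."""
    base = SectionParams(**config.section)
    labels = list(config.treatments) or ["control"]
    per_treatment = {
        label: dataclasses.replace(base, **(overrides or {}))
        for label, overrides in (config.treatments or {"control": {}}).items()
    }
    layout = TMALayout.from_treatments(
        labels,
        config.spheroids_per_treatment,
        cols=config.grid_cols,
        spot_pitch_um=config.spot_pitch_um,
    )
    return layout, base, per_treatment


def quantify_image(image: MultiplexImage, params) -> tuple[list, "object"]:
    """Single-section quantification: detect, classify, aggregate."""
    centers = detect_nuclei(image.nuclear, params, image.pixel_size_um)
    records = classify_cells(image, centers, params)
    return records, quantify_spheroid(records)


def _synthetic_af_map(image: MultiplexImage, seed: int) -> np.ndarray:
    """A smooth, seeded tissue-autofluorescence abundance surface."""
    rng = np.random.default_rng(seed)
    rough = rng.normal(0.0, 1.0, image.shape)
    af = ndimage.gaussian_filter(rough, min(image.shape) / 8.0)
    af = af - af.min()
    peak = af.max() or 1.0
    return 30.0 * af / peak  # comparable to the background intensity scale


def _unmix_roundtrip(
    crop: MultiplexImage, endmembers: EndmemberMatrix, seed: int
) -> MultiplexImage:
    """Forward-mix a crop with synthetic AF, then unmix it back.

    Emulates the multispectral acquisition + Inform-style preprocessing of
    slide mode; the output keeps the crop's metadata.
    """
    stack = generate_spectral_stack(crop, endmembers, _synthetic_af_map(crop, seed))
    out = unmix(stack, endmembers)
    out.metadata.update(crop.metadata)
    return out


def _stats_tables(spheroids: pd.DataFrame, control: str | None):
    """Treatment summaries and Welch comparisons vs control per endpoint."""
    treatments = list(dict.fromkeys(spheroids["treatment"]))
    control = control or treatments[0]
    sum_rows, cmp_rows = [], []
    for endpoint in ENDPOINTS + ("n_tumor", "n_total"):
        groups = {
            t: spheroids.loc[spheroids["treatment"] == t, endpoint].dropna().to_numpy()
            for t in treatments
        }
        for t in treatments:
            if groups[t].size == 0:
                continue
            s = summarize(groups[t], label=t)
            sum_rows.append(
                {
                    "endpoint": endpoint, "treatment": t, "n": s.n,
                    "median": s.median, "q1": s.q1, "q3": s.q3, "iqr": s.iqr,
                    "lower_fence": s.lower_fence, "upper_fence": s.upper_fence,
                    "n_outliers": len(s.outliers),
                    "whisker_low": s.whisker_low, "whisker_high": s.whisker_high,
                }
            )
        for t in treatments:
            if t == control or groups[t].size < 2 or groups[control].size < 2:
                continue
            try:
                r = compare_to_control(groups[t], groups[control])
            except ValueError:
                continue
            cmp_rows.append(
                {
                    "endpoint": endpoint, "treatment": t, "control": control,
                    "t_statistic": r.statistic, "df": r.df, "p_value": r.p_value,
                    "percent_change": r.percent_change,
                }
            )
    return pd.DataFrame(sum_rows), pd.DataFrame(cmp_rows), control


def run_pipeline(config: mio.RunConfig) -> Path:
    """Execute the configured stage(s); return the manifest path.

    Stage errors propagate with the stage named; artifacts written before
    the failure stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    params = config.detection_params()

    slide = None
    layout = None
    crops: list[MultiplexImage] | None = None
    spheroids: pd.DataFrame | None = None

    def _stage(name):
        logger.info("stage %s (seed=%s)", name, config.seed)

    if config.mode in ("simulate", "end-to-end"):
        _stage("simulate")
        layout, base, per_treatment = build_slide_plan(config)
        slide, truths, boxes = generate_tma_slide(
            layout, base, per_treatment, seed=config.seed
        )
        mio.write_multiplex_tiff(slide, out / "slide.tif")
        mio.layout_to_csv(layout, out / "layout.csv")
        truth_rows = []
        for (r, c), truth in truths.items():
            df = truth.cells.copy()
            df.insert(0, "col", c)
            df.insert(0, "row", r)
            df.insert(0, "treatment", layout.treatment_map[(r, c)])
            truth_rows.append(df)
        pd.concat(truth_rows, ignore_index=True).to_csv(
            out / "ground_truth.csv", index=False
        )
        artifacts += [out / "slide.tif", out / "layout.csv", out / "ground_truth.csv"]

    if config.mode == "dearray":
        _stage("load")
        slide = mio.read_multitiff(config.slide_path, config.channel_map)
        layout = mio.layout_from_csv(config.layout_path)

    if config.mode in ("dearray", "end-to-end"):
        _stage("dearray")
        detections = _dearray.detect_spots(slide)
        detections, missing = _dearray.assign_grid(
            detections, layout, slide.pixel_size_um
        )
        crops = _dearray.crop_spots(slide, detections, pad_um=20.0)
        rows = []
        for det in detections:
            rows.append(
                {
                    "row": det.grid[0] if det.grid else "",
                    "col": det.grid[1] if det.grid else "",
                    "treatment": det.treatment or "",
                    "centroid_x": det.centroid[0],
                    "centroid_y": det.centroid[1],
                    "x0": det.bbox[0], "y0": det.bbox[1],
                    "x1": det.bbox[2], "y1": det.bbox[3],
                    "assigned": det.assigned,
                }
            )
        pd.DataFrame(rows).to_csv(out / "spot_manifest.csv", index=False)
        pd.DataFrame(
            [{"row": r, "col": c} for (r, c) in missing]
        ).to_csv(out / "missing_spots.csv", index=False)
        artifacts += [out / "spot_manifest.csv", out / "missing_spots.csv"]
        if config.mode == "dearray":
            crops_dir = out / "crops"
            crops_dir.mkdir(exist_ok=True)
            for crop in crops:
                r, c = crop.metadata["grid"]
                p = crops_dir / f"spot_r{r:02d}_c{c:02d}.tif"
                mio.write_multiplex_tiff(crop, p)
                artifacts.append(p)

    if config.mode == "quantify":
        _stage("load crops")
        crops = [
            mio.read_multitiff(p, config.channel_map)
            for p in sorted(Path(config.crops_dir).glob("*.tif"))
        ]

    if config.mode in ("quantify", "end-to-end") and crops is not None:
        if config.unmix or config.spectra_path:
            _stage("unmix")
            endmembers = (
                EndmemberMatrix.from_csv(config.spectra_path)
                if config.spectra_path
                else default_endmembers()
            )
            crops = [
                _unmix_roundtrip(crop, endmembers, seed=config.seed + i)
                for i, crop in enumerate(crops)
            ]
        _stage("quantify")
        cell_frames, quant_rows = [], []
        for i, crop in enumerate(crops):
            grid = crop.metadata.get("grid", (None, None))
            treatment = crop.metadata.get("treatment", "")
            records, quant = quantify_image(crop, params)
            cell_frames.append(
                mio.cell_records_to_frame(
                    records, treatment=treatment, col=grid[1], row=grid[0]
                )
            )
            quant_rows.append(
                mio.quant_to_row(
                    quant, row=grid[0], col=grid[1], treatment=treatment
                )
            )
        pd.concat(cell_frames, ignore_index=True).to_csv(
            out / "cells.csv", index=False
        )
        spheroids = pd.DataFrame(quant_rows)
        spheroids.to_csv(out / "spheroids.csv", index=False)
        artifacts += [out / "cells.csv", out / "spheroids.csv"]

    if config.mode == "stats" and config.spheroid_csv:
        spheroids = pd.read_csv(config.spheroid_csv)

    if config.mode in ("stats", "end-to-end") and spheroids is not None:
        _stage("stats")
        summaries, comparisons, control = _stats_tables(spheroids, config.control)
        summaries.to_csv(out / "summary.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        artifacts += [out / "summary.csv", out / "comparisons.csv"]
        for endpoint in ENDPOINTS:
            groups = {
                t: g[endpoint].dropna().to_numpy()
                for t, g in spheroids.groupby("treatment", sort=False)
                if g[endpoint].notna().any()
            }
            if not groups:
                continue
            fig = boxplot_figure(groups, ylabel=endpoint)
            p = out / f"boxplot_{endpoint}.png"
            fig.savefig(p, dpi=120)
            import matplotlib.pyplot as plt

            plt.close(fig)
            artifacts.append(p)

    if config.mode == "stats" and config.plate_csv:
        _stage("viability")
        plate = mio.plate_from_csv(config.plate_csv)
        res = viability_analysis(plate)
        rows = [
            {
                "dose": d,
                "relative_mean": res.relative_mean[d],
                "relative_sd": res.relative_sd[d],
                "t_vs_control": res.pairwise.get(d, (np.nan,) * 3)[0],
                "p_raw": res.pairwise.get(d, (np.nan,) * 3)[1],
                "p_bonferroni": res.pairwise.get(d, (np.nan,) * 3)[2],
            }
            for d in plate.doses
        ]
        df = pd.DataFrame(rows)
        df.attrs["anova"] = (res.anova_f, res.anova_p)
        df.insert(1, "anova_f", res.anova_f)
        df.insert(2, "anova_p", res.anova_p)
        df.to_csv(out / "viability.csv", index=False)
        artifacts.append(out / "viability.csv")

    manifest = mio.write_manifest(out, artifacts, config)
    return manifest
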