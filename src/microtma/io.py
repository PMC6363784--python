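"""File formats: multi-page TIFF images, CSV tables, YAML run configs.

All tables are plain CSV with documented headers; images are multi-page
TIFF with one page per channel (order: nuclear, red, green unless stated
otherwise in the embedded JSON description). Round-trips are lossless for
float32 generator output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cellquant import CellRecord, DetectionParams, SpheroidQuant
from .stats import ViabilityPlate
from .types import CHANNELS, MultiplexImage, TMALayout

# ---------------------------------------------------------------------------
# images


def write_multiplex_tiff(image: MultiplexImage, path) -> None:
    """One TIFF page per channel; names and pixel size go in the description."""
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    desc = json.dumps(
        {
            "channels": names,
            "pixel_size_um": image.pixel_size_um,
            "metadata": _jsonable(image.metadata),
        }
    )
    tifffile.imwrite(path, stack, photometric="minisblack", description=desc)


def read_multitiff(path, channel_map: list[str] | None = None) -> MultiplexImage:
    """Read a multi-page TIFF back into a MultiplexImage.

    ``channel_map`` names the pages in order for externally produced files;
    files written by :func:`write_multiplex_tiff` carry their own names. The
    page count must match the channel map.
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    pixel_size = 0.5
    names = None
    if desc:
        try:
            info = json.loads(desc)
            names = info.get("channels")
            pixel_size = info.get("pixel_size_um", pixel_size)
            meta = info.get("metadata", {})
        except (json.JSONDecodeError, AttributeError):
            pass
    if channel_map is not None:
        names = list(channel_map)
    if names is None:
        names = list(CHANNELS)
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"TIFF has {stack.shape[0]} pages but channel map names {len(names)}"
        )
    return MultiplexImage(
        channels={n: stack[i] for i, n in enumerate(names)},
        pixel_size_um=float(pixel_size),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# tables


def ground_truth_to_csv(truth, path) -> None:
    truth.cells.to_csv(path, index=False)


def cell_records_to_frame(
    records: list[CellRecord], **extra_cols
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "x": [r.center[0] for r in records],
            "y": [r.center[1] for r in records],
            "mean_nuclear": [r.mean_nuclear for r in records],
            "mean_red": [r.mean_red for r in records],
            "mean_green": [r.mean_green for r in records],
            "compartment": [r.compartment for r in records],
            "marker": [r.marker for r in records],
        }
    )
    for k, v in extra_cols.items():
        df.insert(0, k, v)
    return df


QUANT_COLUMNS = [
    "n_total", "n_tumor", "n_normal", "n_marker_tumor", "n_marker_normal",
    "pct_tumor", "pct_marker_tumor", "pct_marker_normal",
    "pct_marker_tumor_of_total", "pct_marker_normal_of_total",
]


def quant_to_row(q: SpheroidQuant, **extra) -> dict:
    row = dict(extra)
    row.update({k: getattr(q, k) for k in QUANT_COLUMNS})
    return row


# ---------------------------------------------------------------------------
# layout CSV: header comment carries the grid geometry


def layout_to_csv(layout: TMALayout, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write(
            f"# rows={layout.rows} cols={layout.cols} "
            f"spot_pitch_um={layout.spot_pitch_um}\n"
        )
        f.write("row,col,treatment\n")
        for (r, c) in layout.occupied:
            f.write(f"{r},{c},{layout.treatment_map[(r, c)]}\n")


def layout_from_csv(path) -> TMALayout:
    path = Path(path)
    with path.open() as f:
        header = f.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing geometry header line ('# rows=...')")
        geo = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(f)
    tmap = {
        (int(r.row), int(r.col)): str(r.treatment) for r in df.itertuples()
    }
    return TMALayout(
        rows=int(geo["rows"]),
        cols=int(geo["cols"]),
        spot_pitch_um=float(geo["spot_pitch_um"]),
        treatment_map=tmap,
    )


def plate_to_csv(plate: ViabilityPlate, path) -> None:
    rows = []
    for d in plate.doses:
        for i, v in enumerate(plate.values[d]):
            rows.append({"dose": d, "replicate": i, "value": v,
                         "is_control": d == plate.control})
    pd.DataFrame(rows).to_csv(path, index=False)


def plate_from_csv(path) -> ViabilityPlate:
    df = pd.read_csv(path, dtype={"dose": str})
    doses = list(dict.fromkeys(df["dose"]))
    control = df.loc[df["is_control"], "dose"].iloc[0]
    values = {d: df.loc[df["dose"] == d, "value"].to_numpy() for d in doses}
    return ViabilityPlate(doses=doses, values=values, control=control)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Parsed YAML run configuration for the pipeline stages.

    ``mode`` selects the stage(s): ``simulate``, ``dearray``, ``quantify``,
    ``stats`` or ``end-to-end``. The seed is mandatory and recorded in every
    output manifest.
    """

    mode: str
    out_dir: str
    seed: int
    section: dict = field(default_factory=dict)
    treatments: dict = field(default_factory=dict)  # label -> SectionParams overrides
    spheroids_per_treatment: int = 16
    grid_cols: int = 12
    spot_pitch_um: float = 500.0
    control: str | None = None
    detection: dict = field(default_factory=dict)
    channel_map: list[str] | None = None
    slide_path: str | None = None
    layout_path: str | None = None
    crops_dir: str | None = None
    spheroid_csv: str | None = None
    plate_csv: str | None = None
    spectra_path: str | None = None
    unmix: bool = False

    MODES = ("simulate", "dearray", "quantify", "stats", "end-to-end")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}, got {self.mode!r}")
        if self.seed is None:
            raise ValueError("config field 'seed' is required")
        requires = {
            "dearray": ["slide_path", "layout_path"],
            "quantify": ["crops_dir"],
            "stats": [],
        }
        for name in requires.get(self.mode, []):
            if getattr(self, name) is None:
                raise ValueError(
                    f"mode {self.mode!r} requires config field {name!r}"
                )
        if self.mode == "stats" and not (self.spheroid_csv or self.plate_csv):
            raise ValueError(
                "mode 'stats' requires 'spheroid_csv' and/or 'plate_csv'"
            )
        for name in ("slide_path", "layout_path", "crops_dir",
                     "spheroid_csv", "plate_csv", "spectra_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config field {name!r}: path {p} does not exist")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)


# ---------------------------------------------------------------------------
# manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, artifacts: list[Path], config: RunConfig, path=None):
    """Record every artifact with its checksum plus the config and seed."""
    out_dir = Path(out_dir)
    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "config": _jsonable(asdict(config)),
        "artifacts": [
            {
                "path": str(Path(p).relative_to(out_dir)),
                "sha256": sha256_file(p),
            }
            for p in sorted(Path(p) for p in artifacts)
        ],
    }
    path = path or out_dir / "manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return path
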