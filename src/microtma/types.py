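"""Shared containers for multiplexed spheroid images and TMA layouts.

Conventions used throughout the package:

* images are 2D ``numpy`` arrays indexed ``[row, col]`` (y, x), origin at the
  top-left, pixel-centered 0-based coordinates;
* a point is ``(x, y)`` = ``(col, row)`` in pixels;
* physical lengths are micrometres and are converted to pixels by division
  by ``pixel_size_um`` with round-half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: canonical channel order for dual-IF spheroid sections: nuclear counterstain
#: (Hoechst/DAPI), red (anti-GFP, tumor), green (Ki67 or cleaved caspase-3).
CHANNELS = ("nuclear", "red", "green")


def um_to_px(length_um: float, pixel_size_um: float) -> int:
    """Convert a physical length to whole pixels, rounding half-up."""
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return int(math.floor(length_um / pixel_size_um + 0.5))


@dataclass
class MultiplexImage:
    """Registered single-plane fluorescence channels sharing one pixel grid.

    Parameters
    ----------
    channels
        Mapping of channel name to 2D float array. For dual-IF sections the
        names are ``nuclear``, ``red`` and ``green``; spectral unmixing may
        produce other fluorophore names.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    metadata
        Free-form provenance (spheroid id, treatment, marker name, seed...).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def _get(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"image has no {name!r} channel (has {list(self.channels)})"
            ) from None

    @property
    def nuclear(self) -> np.ndarray:
        return self._get("nuclear")

    @property
    def red(self) -> np.ndarray:
        return self._get("red")

    @property
    def green(self) -> np.ndarray:
        return self._get("green")


@dataclass
class TMALayout:
    """Grid geometry and treatment map of a spheroid microarray slide.

    Spot ``(row, col)`` is centred at ``((col + 0.5) * pitch, (row + 0.5) *
    pitch)`` micrometres from the slide's top-left corner. Only spots present
    in ``treatment_map`` are occupied; the agarose mold caps the grid at 96
    wells.
    """

    rows: int
    cols: int
    spot_pitch_um: float
    treatment_map: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.rows * self.cols > 96:
            raise ValueError(
                f"grid {self.rows}x{self.cols} exceeds the 96-well mold"
            )
        if self.spot_pitch_um <= 0:
            raise ValueError("spot_pitch_um must be > 0")
        for (r, c) in self.treatment_map:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(f"spot ({r}, {c}) outside {self.rows}x{self.cols} grid")

    @classmethod
    def from_treatments(
        cls,
        treatments: list[str],
        spheroids_per_treatment: int,
        cols: int = 12,
        spot_pitch_um: float = 500.0,
    ) -> "TMALayout":
        """Fill a grid row-major with ``spheroids_per_treatment`` spots per arm."""
        if not 1 <= spheroids_per_treatment:
            raise ValueError("spheroids_per_treatment must be >= 1")
        n = len(treatments) * spheroids_per_treatment
        rows = -(-n // cols)
        tmap: dict[tuple[int, int], str] = {}
        i = 0
        for t in treatments:
            for _ in range(spheroids_per_treatment):
                tmap[divmod(i, cols)] = t
                i += 1
        return cls(rows=rows, cols=cols, spot_pitch_um=spot_pitch_um, treatment_map=tmap)

    @property
    def occupied(self) -> list[tuple[int, int]]:
        return sorted(self.treatment_map)

    def node_center_um(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) centre of a grid node in micrometres from the slide origin."""
        return ((col + 0.5) * self.spot_pitch_um, (row + 0.5) * self.spot_pitch_um)

    @property
    def slide_size_um(self) -> tuple[float, float]:
        """(width, height) of the slide canvas in micrometres."""
        return (self.cols * self.spot_pitch_um, self.rows * self.spot_pitch_um)
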