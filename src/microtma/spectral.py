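"""Linear spectral unmixing with autofluorescence removal.

Multispectral scans of stained TMA slides mix the emission spectra of the
fluorophores with a broad tissue autofluorescence (AF) component. Given a
library of endmember spectra (one column per fluorophore plus one AF
column), each pixel spectrum is decomposed by nonnegative least squares into
per-component abundances; the AF abundance is computed and then discarded,
leaving clean per-fluorophore images. Abundances are physical concentrations,
hence the nonnegativity constraint.

Endmember columns are L2-normalized internally and the abundances rescaled
back, so spectra files may store unnormalized shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MultiplexImage

#: reserved component name marking the autofluorescence column
AF_NAME = "AF"


@dataclass
class SpectralStack:
    """A multispectral image cube: ``data[row, col, band]``."""

    data: np.ndarray
    wavelengths: list[float]
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("spectral stack must be 3D (height, width, bands)")
        if len(self.wavelengths) < 2:
            raise ValueError("need at least 2 wavelengths")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"stack has {self.data.shape[2]} bands but "
                f"{len(self.wavelengths)} wavelength labels"
            )
        if self.data.min() < 0:
            raise ValueError("spectral intensities must be nonnegative")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class EndmemberMatrix:
    """Endmember spectra: ``matrix[band, component]`` with component names.

    At most one component may be named ``"AF"``; it is treated as the
    autofluorescence column. The matrix must have full column rank and at
    least as many bands as components, otherwise unmixing is ill-posed.
    """

    matrix: np.ndarray
    names: list[str]
    wavelengths: list[float]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("endmember matrix must be 2D (bands x components)")
        b, c = self.matrix.shape
        if c != len(self.names):
            raise ValueError("one name per endmember column required")
        if b != len(self.wavelengths):
            raise ValueError("one wavelength per endmember row required")
        if self.names.count(AF_NAME) > 1:
            raise ValueError("at most one AF column allowed")
        if b < c:
            raise ValueError(
                f"{b} wavelengths cannot resolve {c} components (need >= {c})"
            )
        if np.linalg.matrix_rank(self.matrix) < c:
            raise ValueError("endmember matrix is rank-deficient")

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]

    @property
    def af_index(self) -> int | None:
        return self.names.index(AF_NAME) if AF_NAME in self.names else None

    @property
    def non_af_names(self) -> list[str]:
        return [n for n in self.names if n != AF_NAME]

    @classmethod
    def from_csv(cls, path) -> "EndmemberMatrix":
        """Read a spectra table: first column wavelength, one column per component."""
        df = pd.read_csv(path)
        wl = df.iloc[:, 0].astype(float).tolist()
        names = list(df.columns[1:])
        return cls(matrix=df.iloc[:, 1:].to_numpy(float), names=names, wavelengths=wl)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "wavelength", self.wavelengths)
        df.to_csv(path, index=False)


def default_endmembers(wavelengths: list[float] | None = None) -> EndmemberMatrix:
    """A plausible 4-band library for (nuclear, red, green) dyes plus AF.

    Synthetic spectra, not an instrument library: each dye peaks in its own
    band with some crosstalk; AF is broad and flat.
    """
    wl = wavelengths or [450.0, 520.0, 570.0, 620.0]
    if len(wl) != 4:
        raise ValueError("default library is defined on 4 bands")
    mat = np.array(
        [  # nuclear  red   green  AF
            [1.00, 0.02, 0.05, 0.6],
            [0.15, 0.05, 1.00, 0.9],
            [0.05, 0.30, 0.25, 1.0],
            [0.02, 1.00, 0.05, 0.8],
        ]
    )
    return EndmemberMatrix(matrix=mat, names=["nuclear", "red", "green", AF_NAME], wavelengths=wl)


def unmix(stack: SpectralStack, endmembers: EndmemberMatrix) -> MultiplexImage:
    """Decompose a spectral stack into nonnegative fluorophore abundances.

    Per pixel, solves ``min ||E a - s||`` subject to ``a >= 0``. The fast
    path is an unconstrained batched least squares; only pixels whose
    unconstrained solution goes negative are re-solved with true NNLS. The
    autofluorescence abundance is computed (so it absorbs its share of the
    signal) and then dropped from the output.
    """
    if not np.allclose(stack.wavelengths, endmembers.wavelengths):
        raise ValueError(
            f"wavelength mismatch: stack {stack.wavelengths} vs "
            f"endmembers {endmembers.wavelengths}"
        )
    E = endmembers.matrix
    scales = np.linalg.norm(E, axis=0)
    En = E / scales
    h, w, b = stack.data.shape
    S = stack.data.reshape(-1, b).T  # bands x pixels
    A, *_ = np.linalg.lstsq(En, S, rcond=None)  # components x pixels

    tol = 1e-8 * max(float(np.abs(A).max()), 1.0)
    bad = np.flatnonzero((A < -tol).any(axis=0))
    if bad.size:
        from scipy.optimize import nnls

        for j in bad:
            A[:, j], _ = nnls(En, S[:, j])
    A = np.clip(A, 0.0, None) / scales[:, None]

    channels = {}
    for i, name in enumerate(endmembers.names):
        if name == AF_NAME:
            continue  # AF absorbed the autofluorescence signal; discard it
        channels[name] = A[i].reshape(h, w)
    return MultiplexImage(
        channels=channels,
        pixel_size_um=stack.pixel_size_um,
        metadata={"unmixed": True, "components": endmembers.non_af_names},
    )
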