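"""Core hyperspectral cube container.

A :class:`HyperCube` is a ``(rows, cols, bands)`` array with a wavelength
grid (nm, strictly increasing) and an ordered provenance list recording the
processing steps applied so far.  Axis order is ``(row, col, band)``,
0-based, everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError

__all__ = ["HyperCube"]


@dataclass
class HyperCube:
    """Band-interleaved hyperspectral volume.

    Parameters
    ----------
    data
        Array of shape ``(rows, cols, bands)``; reflectance is dimensionless,
        raw counts are in sensor counts.
    wavelengths
        Band-center wavelengths in nm, strictly increasing, one per band.
    provenance
        Ordered names of the processing steps already applied.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError(f"cube data must be 3-D (rows, cols, bands), got {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.data.shape[2] != self.wavelengths.size:
            raise ShapeError(
                f"{self.data.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ShapeError("wavelengths must be strictly increasing")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, step: str | None = None) -> "HyperCube":
        """Return a new cube sharing this cube's wavelengths.

        ``step``, when given, is appended to the provenance.
        """
        prov = list(self.provenance) + ([step] if step else [])
        return HyperCube(data, self.wavelengths.copy(), prov)

    def pixel(self, row: int, col: int) -> np.ndarray:
        """Spectrum of one spatial pixel (view, length = bands)."""
        return self.data[row, col, :]
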