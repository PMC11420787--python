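"""Radiometric calibration, cube formation, spectral correction, band removal.

These are the first four preprocessing stages applied to every capture:

1. *Radiometric calibration* converts raw counts to reflectance using
   matched white and dark references, ``R = (Iraw - Idark)/(Iwhite - Idark)``,
   removing the sensor response and the illumination field.
2. *Cube formation* — for the snapshot camera, cropping the sensor frame to
   its active filter zone and rearranging the 5x5 filter mosaic into a
   25-band cube (demosaicing); for the linescan camera, stitching the
   acquired lines into a cube.
3. *Spectral correction* (snapshot only) right-multiplies each pixel
   spectrum by the sensor's spectral correction matrix to undo filter
   crosstalk.
4. *Band removal* (linescan only) keeps only the effective bands inside a
   wavelength window (400–1000 nm by default).

Calibration operates elementwise, so it commutes with the purely
positional cube-formation step; it is applied in mosaic/line space first,
matching the stage order of the acquisition software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cube import HyperCube
from .errors import (
    DegenerateReferenceError,
    EmptySelectionError,
    ShapeError,
)

__all__ = [
    "CalibrationResult",
    "calibrate",
    "calibrate_full",
    "crop_active_area",
    "demosaic",
    "remosaic",
    "stitch_lines",
    "apply_spectral_correction",
    "remove_bands",
    "scm_from_crosstalk",
]

#: counts below which a white-minus-dark denominator is treated as degenerate
DENOM_EPS = 1e-9


@dataclass
class CalibrationResult:
    reflectance: np.ndarray
    invalid: np.ndarray       # True where the denominator was degenerate
    out_of_range: np.ndarray  # True where R fell outside [0, 1]


def calibrate_full(
    i_raw: np.ndarray,
    i_white: np.ndarray,
    i_dark: np.ndarray,
    denom_eps: float = DENOM_EPS,
    clip: bool = False,
) -> CalibrationResult:
    """Elementwise reflectance calibration with bookkeeping masks.

    ``R = (Iraw - Idark) / (Iwhite - Idark)`` per element.  Elements whose
    denominator is ``<= denom_eps`` are flagged invalid and set to 0.
    Reflectance outside [0, 1] can legitimately occur (specular highlights,
    noise); by default the values are preserved and only recorded in the
    ``out_of_range`` mask, ``clip=True`` maps them into [0, 1].
    """
    raw = np.asarray(i_raw, dtype=float)
    white = np.asarray(i_white, dtype=float)
    dark = np.asarray(i_dark, dtype=float)
    if not (raw.shape == white.shape == dark.shape):
        raise ShapeError(
            f"capture shapes differ: raw {raw.shape}, white {white.shape}, dark {dark.shape}"
        )
    denom = white - dark
    invalid = denom <= denom_eps
    if np.all(invalid):
        raise DegenerateReferenceError("white and dark references coincide everywhere")
    safe = np.where(invalid, 1.0, denom)
    r = (raw - dark) / safe
    r = np.where(invalid, 0.0, r)
    oob = (r < 0) | (r > 1)
    if clip:
        r = np.clip(r, 0.0, 1.0)
    return CalibrationResult(reflectance=r, invalid=invalid, out_of_range=oob)


def calibrate(
    i_raw: np.ndarray,
    i_white: np.ndarray,
    i_dark: np.ndarray,
    denom_eps: float = DENOM_EPS,
    clip: bool = False,
) -> np.ndarray:
    """Reflectance ``(Iraw - Idark)/(Iwhite - Idark)``; see calibrate_full."""
    return calibrate_full(i_raw, i_white, i_dark, denom_eps, clip).reflectance


def crop_active_area(frame: np.ndarray, crop_rows: int = 3, crop_cols: int = 3) -> np.ndarray:
    """Drop the last ``crop_rows`` rows and ``crop_cols`` columns.

    The snapshot sensor's spectral filters cover only the active filter
    zone, which omits the last three rows and columns of the full frame.
    Retained values are unchanged.
    """
    frame = np.asarray(frame)
    if crop_rows < 0 or crop_cols < 0:
        raise ValueError("crop sizes must be non-negative")
    if crop_rows >= frame.shape[0] or crop_cols >= frame.shape[1]:
        raise ValueError(
            f"crop ({crop_rows}, {crop_cols}) does not fit a {frame.shape} frame"
        )
    return frame[: frame.shape[0] - crop_rows, : frame.shape[1] - crop_cols]


def demosaic(
    frame: np.ndarray,
    mosaic_size: int = 5,
    band_centers: np.ndarray | None = None,
) -> HyperCube:
    """Rearrange a mosaic frame into a cube, one band per filter position.

    Band ``b`` of output pixel ``(y, x)`` is sensor pixel
    ``(m*y + b // m, m*x + b % m)`` — row-major within each m x m tile.
    Spatial resolution drops by a factor of ``mosaic_size`` per axis.
    """
    frame = np.asarray(frame)
    m = int(mosaic_size)
    rows, cols = frame.shape
    if rows % m or cols % m:
        raise ValueError(
            f"frame {frame.shape} not divisible by mosaic size {m}; "
            "crop to the active filter zone first (crop_active_area)"
        )
    cube = (
        frame.reshape(rows // m, m, cols // m, m)
        .transpose(0, 2, 1, 3)
        .reshape(rows // m, cols // m, m * m)
    )
    if band_centers is None:
        band_centers = np.arange(m * m, dtype=float)
    return HyperCube(cube, band_centers, provenance=["demosaic"])


def remosaic(cube: HyperCube | np.ndarray, mosaic_size: int = 5) -> np.ndarray:
    """Exact inverse of :func:`demosaic` (bit-exact round trip)."""
    data = cube.data if isinstance(cube, HyperCube) else np.asarray(cube)
    m = int(mosaic_size)
    if data.ndim != 3 or data.shape[2] != m * m:
        raise ValueError(f"cube must have {m * m} bands, got shape {data.shape}")
    ny, nx = data.shape[:2]
    return (
        data.reshape(ny, nx, m, m)
        .transpose(0, 2, 1, 3)
        .reshape(ny * m, nx * m)
    )


def stitch_lines(
    lines: Sequence[np.ndarray],
    wavelengths: np.ndarray | None = None,
) -> HyperCube:
    """Join pushbroom lines into a cube, in acquisition order, no overlap.

    Each line is ``(line_length, bands)``; line ``i`` becomes cube column
    ``i``, so the result is ``(line_length, n_lines, bands)``.
    """
    if len(lines) < 1:
        raise ValueError("need at least one line")
    first = np.asarray(lines[0])
    if first.ndim != 2:
        raise ShapeError("each line must be a 2-D (line_length, bands) array")
    for i, ln in enumerate(lines):
        if np.asarray(ln).shape != first.shape:
            raise ShapeError(
                f"line {i} has shape {np.asarray(ln).shape}, expected {first.shape}"
            )
    data = np.stack([np.asarray(ln) for ln in lines], axis=1)
    if wavelengths is None:
        wavelengths = np.arange(first.shape[1], dtype=float)
    return HyperCube(data, wavelengths, provenance=["stitch_lines"])


def scm_from_crosstalk(crosstalk: np.ndarray) -> np.ndarray:
    """Spectral correction matrix that undoes a crosstalk mixing matrix.

    The simulated sensor mixes bands by right-multiplying each pixel
    spectrum with a row-stochastic crosstalk matrix; its inverse plays the
    role of the manufacturer-supplied correction matrix.
    """
    x = np.asarray(crosstalk, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ShapeError("crosstalk matrix must be square")
    return np.linalg.inv(x)


def apply_spectral_correction(cube: HyperCube, scm: np.ndarray) -> HyperCube:
    """Right-multiply each pixel spectrum (row vector) by the SCM.

    ``Rsc[y, x, :] = R[y, x, :] @ SCM`` — linear in the cube.
    """
    scm = np.asarray(scm, dtype=float)
    if scm.ndim != 2 or scm.shape[0] != cube.bands:
        raise ShapeError(
            f"SCM shape {scm.shape} incompatible with {cube.bands}-band cube"
        )
    if not np.all(np.isfinite(scm)):
        raise ValueError("SCM has non-finite entries")
    corrected = cube.data @ scm
    return cube.with_data(corrected, step="spectral_correction")


def remove_bands(cube: HyperCube, keep_min_nm: float, keep_max_nm: float) -> HyperCube:
    """Keep only bands with ``keep_min_nm <= lambda <= keep_max_nm`` (inclusive).

    Used to extract the linescan camera's effective bands from the wider
    sensor-sensitive range.
    """
    keep = (cube.wavelengths >= keep_min_nm) & (cube.wavelengths <= keep_max_nm)
    if not np.any(keep):
        raise EmptySelectionError(
            f"no band inside [{keep_min_nm:g}, {keep_max_nm:g}] nm "
            f"(grid spans [{cube.wavelengths[0]:g}, {cube.wavelengths[-1]:g}] nm)"
        )
    out = HyperCube(
        cube.data[:, :, keep],
        cube.wavelengths[keep],
        provenance=list(cube.provenance) + ["remove_bands"],
    )
    return out
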