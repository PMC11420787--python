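"""Spectral similarity metrics and ROI spectrum extraction.

Implements the inter-camera comparison machinery: per-pixel min-max
normalization, ROI pixel extraction with fair random subsampling (the
higher-resolution linescan ROI is subsampled to the same 25 pixels the
snapshot ROI holds), nearest-neighbour wavelength matching between the two
cameras' grids, the SAM / GFC / RMSE / Pearson metrics, and robust
interquartile-range summaries of metric distributions across patients.

Metric conventions
------------------
SAM   (2/pi) * arccos( <x,y> / (|x| |y|) ), mapped onto [0, 1] for
      non-negative spectra; 0 = identical direction.
GFC   |<x,y>| / (|x| |y|); 1 = proportional spectra.
RMSE  sqrt(mean((x - y)^2)); 0 = identical, bounded by 1 when the data is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cube import HyperCube
from .errors import ShapeError

__all__ = [
    "Spectrum",
    "BandPairing",
    "SimilarityRecord",
    "DistributionSummary",
    "minmax_normalize",
    "extract_roi_pixels",
    "subsample_pixels",
    "mean_std_spectrum",
    "match_wavelengths",
    "sam",
    "gfc",
    "rmse",
    "pearson",
    "compare_cameras",
    "summarize_distribution",
]


@dataclass
class Spectrum:
    """Mean +/- SD spectral signature of one ROI."""

    wavelengths: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_pixels: int
    tissue: str = ""
    camera: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.wavelengths.shape == self.mean.shape == self.sd.shape):
            raise ShapeError("wavelengths, mean and sd must share one shape")
        if np.any(self.sd < -1e-12):
            raise ValueError("negative standard deviation")


@dataclass
class BandPairing:
    """Nearest-wavelength pairing between two band grids.

    ``pairs`` rows are ``(index_a, index_b, lambda_a, lambda_b, |dlambda|)``,
    one per band of the shorter grid (grid a).
    """

    index_a: np.ndarray
    index_b: np.ndarray
    lambda_a: np.ndarray
    lambda_b: np.ndarray
    delta: np.ndarray

    def __len__(self) -> int:
        return int(self.index_a.size)


@dataclass
class SimilarityRecord:
    patient_id: str
    tissue: str
    sam: float
    gfc: float
    rmse: float
    normalized: bool


@dataclass
class DistributionSummary:
    q1: float
    q3: float
    iqr: float
    median: float
    mean: float
    n: int


# ---------------------------------------------------------------------------
# Normalization and ROI extraction
# ---------------------------------------------------------------------------

def minmax_normalize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel min-max normalization onto [0, 1].

    ``values`` is ``(..., bands)``; each trailing spectrum is normalized
    independently: ``(x - min(x)) / (max(x) - min(x))``.  Degenerate
    (constant) spectra map to all zeros and are flagged.

    Returns ``(normalized, degenerate_mask)`` where the mask has the
    leading shape of ``values``.
    """
    x = np.asarray(values, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("min-max normalization needs at least 2 bands")
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    degenerate = (span <= 0).squeeze(-1)
    safe = np.where(span > 0, span, 1.0)
    out = (x - lo) / safe
    out = np.where(span > 0, out, 0.0)
    return out, np.asarray(degenerate, bool)


def extract_roi_pixels(
    cube: HyperCube, pixel_list: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Stack the spectra of the listed ``(row, col)`` pixels.

    Returns an ``(n_pixels, bands)`` array in list order; an empty list
    yields an empty ``(0, bands)`` table.
    """
    if len(pixel_list) == 0:
        return np.empty((0, cube.bands), dtype=cube.data.dtype)
    rows = np.asarray([p[0] for p in pixel_list], dtype=int)
    cols = np.asarray([p[1] for p in pixel_list], dtype=int)
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= cube.rows or cols.max() >= cube.cols):
        raise IndexError("ROI pixel outside cube bounds")
    return cube.data[rows, cols, :]


def subsample_pixels(
    pixel_list: Sequence[tuple[int, int]], n: int, seed: int
) -> list[tuple[int, int]]:
    """Draw ``n`` distinct pixels uniformly without replacement.

    Deterministic given ``seed`` (PCG64 generator); used to reduce the
    larger linescan ROI to the snapshot's 25 pixels for a fair comparison.
    """
    if n > len(pixel_list):
        raise ValueError(f"cannot sample {n} pixels from {len(pixel_list)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pixel_list), size=n, replace=False)
    return [tuple(pixel_list[i]) for i in idx]


def mean_std_spectrum(
    pixel_spectra: np.ndarray,
    wavelengths: np.ndarray,
    normalize_first: bool = False,
    tissue: str = "",
    camera: str = "",
) -> Spectrum:
    """Mean and per-band sample SD over ROI pixels.

    With ``normalize_first`` each pixel spectrum is min-max normalized
    before averaging (the normalization is per spectral pixel, so it is
    applied before, not after, the mean).  SD uses ddof=1 when more than
    one pixel contributes, else 0.
    """
    px = np.asarray(pixel_spectra, dtype=float)
    if px.ndim != 2 or px.shape[0] < 1:
        raise ValueError("need a non-empty (n_pixels, bands) array")
    if normalize_first:
        px, _ = minmax_normalize(px)
    ddof = 1 if px.shape[0] > 1 else 0
    return Spectrum(
        wavelengths=np.asarray(wavelengths, float),
        mean=px.mean(axis=0),
        sd=px.std(axis=0, ddof=ddof),
        n_pixels=px.shape[0],
        tissue=tissue,
        camera=camera,
        normalized=normalize_first,
    )


# ---------------------------------------------------------------------------
# Wavelength matching
# ---------------------------------------------------------------------------

def match_wavelengths(grid_a: np.ndarray, grid_b: np.ndarray) -> BandPairing:
    """Pair each band of the shorter grid a with its nearest band in grid b.

    Ties (a wavelength exactly midway between two grid-b bands) break toward
    the lower wavelength.
    """
    a = np.asarray(grid_a, dtype=float)
    b = np.asarray(grid_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(a) <= 0) or np.any(np.diff(b) <= 0):
        raise ValueError("grids must be strictly increasing")
    # distance matrix argmin returns the first (lower-index, hence lower
    # wavelength) minimizer, which implements the tie rule directly
    d = np.abs(b[None, :] - a[:, None])
    jb = d.argmin(axis=1)
    return BandPairing(
        index_a=np.arange(a.size),
        index_b=jb,
        lambda_a=a,
        lambda_b=b[jb],
        delta=np.abs(a - b[jb]),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ShapeError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def sam(x: np.ndarray, y: np.ndarray) -> float:
    """Spectral angle mapper, scaled onto [0, 1].

    ``(2/pi) * arccos(<x,y> / (|x| |y|))``: 0 for identical direction, 1
    for orthogonal spectra.  Scale-invariant; for non-negative spectra the
    angle cannot exceed pi/2, hence the [0, 1] range.
    """
    x, y = _as_pair(x, y)
    if x.size < 2:
        raise ValueError("SAM needs at least 2 bands")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ZeroDivisionError("SAM undefined for a zero spectrum")
    c = np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)
    return float(2.0 / np.pi * np.arccos(c))


def gfc(x: np.ndarray, y: np.ndarray) -> float:
    """Goodness-of-fit coefficient ``|<x,y>| / (|x| |y|)`` in [0, 1]."""
    x, y = _as_pair(x, y)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ZeroDivisionError("GFC undefined for a zero spectrum")
    return float(min(abs(np.dot(x, y)) / (nx * ny), 1.0))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean square error ``sqrt(mean((x-y)^2))``."""
    x, y = _as_pair(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    x, y = _as_pair(x, y)
    if x.size < 2:
        raise ValueError("Pearson correlation needs at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def compare_cameras(
    spectrum_a: Spectrum,
    spectrum_b: Spectrum,
    pairing: BandPairing,
    patient_id: str = "",
) -> SimilarityRecord:
    """SAM/GFC/RMSE between two cameras' mean spectra on matched bands.

    ``spectrum_a`` is the snapshot (arbitrary) signal, ``spectrum_b`` the
    linescan reference; both are restricted to the paired bands first.
    """
    if pairing.index_a.max() >= spectrum_a.mean.size:
        raise ShapeError("pairing exceeds spectrum_a band count")
    if pairing.index_b.max() >= spectrum_b.mean.size:
        raise ShapeError("pairing exceeds spectrum_b band count")
    if spectrum_a.normalized != spectrum_b.normalized:
        raise ValueError("cannot mix normalized and unnormalized spectra")
    x = spectrum_a.mean[pairing.index_a]
    y = spectrum_b.mean[pairing.index_b]
    return SimilarityRecord(
        patient_id=patient_id,
        tissue=spectrum_a.tissue or spectrum_b.tissue,
        sam=sam(x, y),
        gfc=gfc(x, y),
        rmse=rmse(x, y),
        normalized=spectrum_a.normalized,
    )


def summarize_distribution(values: Sequence[float]) -> DistributionSummary:
    """Quartile summary with IQR = Q3 - Q1.

    Quartiles use linear interpolation between order statistics (the
    numpy default, type-7).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("cannot summarize an empty distribution")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return DistributionSummary(
        q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
        median=float(med), mean=float(v.mean()), n=int(v.size),
    )
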