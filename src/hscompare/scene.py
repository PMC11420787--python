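"""Synthetic tissue phantoms and dual-camera capture simulation.

Everything downstream of acquisition (calibration, cube formation, noise
filtering, similarity metrics, chromophore matching) is exercised on
simulated data, so this module is first-class, tested code rather than a
fixture.  It emulates:

* a two-tissue reflectance phantom built from Beer–Lambert chromophore
  mixtures — a "healthy" disk with a higher oxy-hemoglobin fraction and a
  "pathological" disk with a higher deoxy-hemoglobin fraction, each
  surrounded by a dark rubber-ring annulus used to co-locate the two
  cameras' regions of interest;
* the 5x5 snapshot-mosaic camera: Gaussian band integration, filter
  crosstalk, an additive ~850 nm contamination peak from the rangefinder
  laser that is on during snapshot captures, 8-bit quantization, and the
  active-filter-zone geometry (full sensor minus the last three rows and
  columns);
* the pushbroom linescan camera: 394 bands acquired line by line at
  16-bit depth, no laser peak (the rangefinder is off during scans);
* white and dark reference captures under identical geometry.

Sensor counts for a pixel seeing reflectance R are
``dark_level + gain * R (+ laser peak) + read noise + signal-proportional
noise``, rounded and clipped to the ADC range; the white reference images a
unit-reflectance flat target and the dark reference is read noise on the
dark level only.  ``gain`` is chosen so the white reference sits at a
fixed fraction of full scale and never saturates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .chromophores import ChromophoreSpectrum, synthetic_chromophore_library
from .errors import CoverageError, GeometryError, ShapeError

__all__ = [
    "TISSUE_LABELS",
    "PhantomGeometry",
    "PhantomScene",
    "CameraSpec",
    "NoiseModel",
    "CaptureSet",
    "RoiMasks",
    "generate_phantom",
    "simulate_snapshot_capture",
    "simulate_linescan_capture",
    "make_roi_masks",
    "band_response_matrix",
    "default_crosstalk_matrix",
    "snapshot_camera",
    "linescan_camera",
    "default_snapshot_noise",
    "default_linescan_noise",
    "SNAPSHOT_BAND_MIN_NM",
    "SNAPSHOT_BAND_MAX_NM",
    "LINESCAN_SENSOR_MIN_NM",
    "LINESCAN_SENSOR_MAX_NM",
]

TISSUE_LABELS = {"background": 0, "healthy": 1, "pathological": 2, "ring": 3}

# Snapshot band centers: 25 uniform points over the shared comparison range.
SNAPSHOT_BAND_MIN_NM = 659.95
SNAPSHOT_BAND_MAX_NM = 951.42
# Linescan sensor-sensitive range (394 bands before effective-band removal).
LINESCAN_SENSOR_MIN_NM = 365.0
LINESCAN_SENSOR_MAX_NM = 1004.0

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PhantomGeometry:
    """Layout and composition of the synthetic two-tissue phantom.

    Concentrations are dimensionless scale factors multiplying each
    chromophore's reference absorption table (so 0.01 of the whole-blood
    HbO2 table means a 1% blood-volume fraction at full oxygenation).
    ``flat_mu_a`` adds a wavelength-flat absorption offset per tissue,
    standing in for non-chromophore losses, and ``ring_mu_a`` darkens the
    rubber-ring annuli.  ``heterogeneity`` scales a smooth random spatial
    field applied multiplicatively to concentrations and path length so
    ROI pixels differ in brightness the way a curved tissue surface does.
    """

    healthy_center: tuple[int, int] | None = None
    pathological_center: tuple[int, int] | None = None
    disk_radius: int = 16
    ring_width: int = 3
    snapshot_ratio: int = 4
    base_path_length_cm: float = 0.5
    heterogeneity: float = 0.15
    path_length_jitter: float = 0.2
    ring_mu_a: float = 2.0
    compositions: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "healthy": {"HbO2": 0.012, "Hb": 0.004, "water": 0.70, "fat": 0.10,
                    "cyt_aa3_ox": 0.004, "cyt_b_ox": 0.004, "cyt_c_ox": 0.004},
        "pathological": {"HbO2": 0.008, "Hb": 0.012, "water": 0.75, "fat": 0.05,
                         "cyt_aa3_ox": 0.004, "cyt_b_ox": 0.004, "cyt_c_ox": 0.004},
        "background": {"HbO2": 0.004, "Hb": 0.002, "water": 0.55, "fat": 0.08},
    })
    flat_mu_a: dict[str, float] = field(default_factory=lambda: {
        "healthy": 0.45, "pathological": 0.90, "background": 0.30,
    })


@dataclass
class PhantomScene:
    """A synthetic reflectance scene with its generating maps."""

    width: int
    height: int
    wavelength_grid: np.ndarray
    concentration_maps: dict[str, np.ndarray]
    path_length_map: np.ndarray
    tissue_label_map: np.ndarray
    reflectance: np.ndarray  # (height, width, n_wavelengths) in [1e-6, 1]
    geometry: PhantomGeometry
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.height, self.width
        if self.reflectance.shape != (h, w, self.wavelength_grid.size):
            raise ShapeError("reflectance shape inconsistent with scene dims")
        for name, m in self.concentration_maps.items():
            if m.shape != (h, w):
                raise ShapeError(f"concentration map {name!r} shape {m.shape} != ({h}, {w})")
        if self.path_length_map.shape != (h, w) or self.tissue_label_map.shape != (h, w):
            raise ShapeError("path length / label map shape mismatch")


@dataclass
class CameraSpec:
    """Static description of one camera's sensor geometry and bands."""

    name: str
    sensor_rows: int
    sensor_cols: int
    bit_depth: int
    band_centers: np.ndarray
    band_fwhm: float
    mosaic_size: int | None = None
    crop_rows: int = 0
    crop_cols: int = 0
    line_length: int | None = None

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if self.band_centers.size > 1 and not np.all(np.diff(self.band_centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        if self.name == "snapshot":
            if self.mosaic_size is None or self.mosaic_size ** 2 != self.band_centers.size:
                raise ValueError(
                    f"snapshot needs mosaic_size^2 == n_bands, got "
                    f"{self.mosaic_size}^2 vs {self.band_centers.size}"
                )
        elif self.name == "linescan":
            if self.line_length is None or self.line_length < 1:
                raise ValueError("linescan needs a positive line_length")
        else:
            raise ValueError(f"camera name must be 'snapshot' or 'linescan', got {self.name!r}")

    @property
    def full_scale(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def n_bands(self) -> int:
        return int(self.band_centers.size)


@dataclass
class NoiseModel:
    """Additive sensor-noise description; the seed fixes every draw.

    ``read_noise_sd`` (counts) is additive Gaussian read noise;
    ``shot_noise_scale`` adds Gaussian noise with SD proportional to the
    signal (shot-like but additive, matching the additive-noise
    assumption of the denoising stage).  The laser contamination peak is an
    additive Gaussian bump in band space centered near 850 nm, applied to
    the raw snapshot capture only, never to references.  ``dark_level``
    and ``white_fill`` set the acquisition operating point (dark offset in
    counts and the white-reference level as a fraction of full scale,
    below saturation).
    """

    read_noise_sd: float = 0.0
    shot_noise_scale: float = 0.0
    lidar_peak_center: float = 850.0
    lidar_peak_amplitude: float = 0.0
    lidar_peak_fwhm: float = 30.0
    seed: int = 0
    dark_level: float = 4.0
    white_fill: float = 0.92

    def __post_init__(self) -> None:
        for name in ("read_noise_sd", "shot_noise_scale", "lidar_peak_amplitude",
                     "lidar_peak_fwhm", "dark_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.white_fill < 1.0:
            raise ValueError("white_fill must lie in (0, 1) to avoid saturation")


@dataclass
class CaptureSet:
    """A raw capture with its matched white and dark references."""

    i_raw: np.ndarray
    i_white: np.ndarray
    i_dark: np.ndarray
    camera: CameraSpec

    def __post_init__(self) -> None:
        if not (self.i_raw.shape == self.i_white.shape == self.i_dark.shape):
            raise ShapeError("raw/white/dark shapes differ")
        full = self.camera.full_scale
        if int(self.i_white.max()) >= full:
            raise ValueError("white reference is saturated")
        frac = float(np.mean(self.i_white > self.i_dark))
        if frac < 0.99:
            raise ValueError(
                f"white exceeds dark on only {frac:.1%} of pixels (need >= 99%)"
            )


@dataclass
class RoiMasks:
    """Per-tissue ROI pixel lists for each camera.

    Snapshot lists are in snapshot-cube coordinates (exactly
    ``roi_size x roi_size`` pixels); linescan lists are in scene/linescan
    coordinates and larger by the resolution ratio.
    """

    snapshot: dict[str, list[tuple[int, int]]]
    linescan: dict[str, list[tuple[int, int]]]
    roi_size: int
    snapshot_ratio: int


# ---------------------------------------------------------------------------
# Camera factories
# ---------------------------------------------------------------------------

def snapshot_camera(cube_rows: int = 24, cube_cols: int = 30) -> CameraSpec:
    """Snapshot 5x5-mosaic camera spec.

    Sensor dims are ``5 * cube + 3`` so that cropping the 3-row/3-column
    inactive border leaves a mosaic-divisible active zone (the full-size
    sensor is 2048x1088 -> active 2045x1085 -> 409x217x25 cube; the default
    here is a desk-scale sensor with the same structure).  25 band centers
    are spaced uniformly over 659.95-951.42 nm, FWHM 15 nm.
    """
    return CameraSpec(
        name="snapshot",
        sensor_rows=5 * cube_rows + 3,
        sensor_cols=5 * cube_cols + 3,
        bit_depth=8,
        band_centers=np.linspace(SNAPSHOT_BAND_MIN_NM, SNAPSHOT_BAND_MAX_NM, 25),
        band_fwhm=15.0,
        mosaic_size=5,
        crop_rows=3,
        crop_cols=3,
    )


def linescan_camera(line_length: int = 96, n_bands: int = 394) -> CameraSpec:
    """Pushbroom linescan camera spec.

    394 bands uniform over the 365-1004 nm sensor-sensitive range (369 of
    which survive the 400-1000 nm effective-band removal), 16-bit ADC,
    FWHM 5.8 nm.  The full-size instrument has line_length 1600.
    """
    return CameraSpec(
        name="linescan",
        sensor_rows=line_length,
        sensor_cols=1,
        bit_depth=16,
        band_centers=np.linspace(LINESCAN_SENSOR_MIN_NM, LINESCAN_SENSOR_MAX_NM, n_bands),
        band_fwhm=5.8,
        line_length=line_length,
    )


def default_snapshot_noise(seed: int = 0) -> NoiseModel:
    """Acquisition-condition noise for the snapshot camera (laser on)."""
    return NoiseModel(read_noise_sd=1.0, shot_noise_scale=0.01,
                      lidar_peak_amplitude=12.0, lidar_peak_fwhm=30.0, seed=seed)


def default_linescan_noise(seed: int = 0) -> NoiseModel:
    """Acquisition-condition noise for the linescan camera (laser off)."""
    return NoiseModel(read_noise_sd=30.0, shot_noise_scale=0.002,
                      lidar_peak_amplitude=0.0, seed=seed, dark_level=400.0)


# ---------------------------------------------------------------------------
# Band integration and crosstalk
# ---------------------------------------------------------------------------

def band_response_matrix(
    wavelength_grid: np.ndarray, band_centers: np.ndarray, fwhm: float
) -> np.ndarray:
    """Gaussian spectral-response weights, grid x bands, columns sum to 1.

    Each band integrates the scene spectrum with a Gaussian of the given
    FWHM truncated at +/-3 sigma.
    """
    grid = np.asarray(wavelength_grid, dtype=float)
    centers = np.asarray(band_centers, dtype=float)
    sigma = fwhm / _FWHM_TO_SIGMA
    w = np.exp(-0.5 * ((grid[:, None] - centers[None, :]) / sigma) ** 2)
    w[np.abs(grid[:, None] - centers[None, :]) > 3.0 * sigma] = 0.0
    sums = w.sum(axis=0)
    if np.any(sums <= 0):
        bad = centers[sums <= 0]
        raise CoverageError(f"band centers {bad} have no support on the scene grid")
    return w / sums


def default_crosstalk_matrix(n_bands: int, leak: float = 0.05) -> np.ndarray:
    """Row-stochastic nearest-neighbour crosstalk mixing matrix.

    Each band leaks ``leak`` of its signal into each adjacent band; rows
    renormalize to 1.  Its inverse serves as the spectral correction
    matrix in the simulated pipeline.
    """
    if not 0 <= leak < 0.5:
        raise ValueError("leak must lie in [0, 0.5)")
    x = np.eye(n_bands)
    for i in range(n_bands):
        if i > 0:
            x[i, i - 1] = leak
        if i + 1 < n_bands:
            x[i, i + 1] = leak
    return x / x.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float = 8.0) -> np.ndarray:
    """Zero-mean, unit-ish-amplitude smooth random field in [-1, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _disk_mask(h: int, w: int, center: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def generate_phantom(
    width: int = 120,
    height: int = 96,
    chromophore_tables: dict[str, ChromophoreSpectrum] | None = None,
    geometry: PhantomGeometry | None = None,
    seed: int = 0,
    wavelength_grid: np.ndarray | None = None,
) -> PhantomScene:
    """Build a two-tissue Beer–Lambert reflectance phantom.

    Per pixel, absorbance is ``A(lambda) = l * (sum_k c_k mu_a_k(lambda)
    + flat)`` and reflectance is ``10^(-A)`` clipped to [1e-6, 1].  The
    healthy disk carries a higher HbO2 fraction, the pathological disk a
    higher Hb fraction and a larger flat offset (so it is darker), and
    both disks sit inside dark ring annuli.  A seeded smooth field
    modulates concentrations and path length for realistic within-ROI
    brightness variation; identical (arguments, seed) give a bit-identical
    scene.

    Raises :class:`CoverageError` when a supplied chromophore table does
    not cover the scene wavelength grid.
    """
    if wavelength_grid is None:
        wavelength_grid = np.arange(360.0, 1010.0 + 0.5, 1.0)
    grid = np.asarray(wavelength_grid, dtype=float)
    geom = geometry if geometry is not None else PhantomGeometry()
    if chromophore_tables is None:
        tables = synthetic_chromophore_library(grid)
    else:
        tables = {
            name: ChromophoreSpectrum(name, grid.copy(), t.interp(grid), t.unit_kind)
            for name, t in chromophore_tables.items()
        }
    for name, t in tables.items():
        if t.unit_kind != "absorption_coefficient":
            raise ValueError(f"phantom tables must be mu_a (cm^-1); {name!r} is {t.unit_kind}")

    h, w = int(height), int(width)
    hc = geom.healthy_center or (h // 2, int(round(w * 0.28)))
    pc = geom.pathological_center or (h // 2, int(round(w * 0.72)))
    r_in, r_out = geom.disk_radius, geom.disk_radius + geom.ring_width
    for name, center in (("healthy", hc), ("pathological", pc)):
        if not (r_out <= center[0] < h - r_out and r_out <= center[1] < w - r_out):
            raise GeometryError(f"{name} ring at {center} does not fit a {h}x{w} scene")

    labels = np.zeros((h, w), dtype=np.int8)
    masks = {}
    for name, center in (("healthy", hc), ("pathological", pc)):
        disk = _disk_mask(h, w, center, r_in)
        ring = _disk_mask(h, w, center, r_out) & ~disk
        labels[disk] = TISSUE_LABELS[name]
        labels[ring] = TISSUE_LABELS["ring"]
        masks[name] = disk

    rng = np.random.default_rng(seed)
    conc_field = 1.0 + geom.heterogeneity * _smooth_field((h, w), rng)
    path_field = 1.0 + geom.path_length_jitter * _smooth_field((h, w), rng)
    path_length = geom.base_path_length_cm * np.clip(path_field, 0.2, None)

    chrom_names = sorted({k for comp in geom.compositions.values() for k in comp})
    missing = [k for k in chrom_names if k not in tables]
    if missing:
        raise KeyError(f"composition references unknown chromophores {missing}")

    conc_maps: dict[str, np.ndarray] = {
        k: np.zeros((h, w)) for k in chrom_names
    }
    flat = np.zeros((h, w))
    region_masks = {
        "healthy": masks["healthy"],
        "pathological": masks["pathological"],
        "background": labels == TISSUE_LABELS["background"],
    }
    for tissue, mask in region_masks.items():
        comp = geom.compositions.get(tissue, {})
        for k, c in comp.items():
            conc_maps[k][mask] = c
        flat[mask] = geom.flat_mu_a.get(tissue, 0.0)
    for m in conc_maps.values():
        m *= np.clip(conc_field, 0.2, None)

    mu_a = np.zeros((h, w, grid.size))
    for k in chrom_names:
        mu_a += conc_maps[k][:, :, None] * tables[k].values[None, None, :]
    mu_a += flat[:, :, None]
    mu_a[labels == TISSUE_LABELS["ring"], :] = geom.ring_mu_a

    absorbance = mu_a * path_length[:, :, None]
    reflectance = np.clip(10.0 ** (-absorbance), 1e-6, 1.0)

    return PhantomScene(
        width=w, height=h, wavelength_grid=grid,
        concentration_maps=conc_maps, path_length_map=path_length,
        tissue_label_map=labels, reflectance=reflectance,
        geometry=replace(geom, healthy_center=hc, pathological_center=pc),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Capture simulation
# ---------------------------------------------------------------------------

def _lidar_bump(spec: CameraSpec, noise: NoiseModel) -> np.ndarray:
    sigma = noise.lidar_peak_fwhm / _FWHM_TO_SIGMA
    return noise.lidar_peak_amplitude * np.exp(
        -0.5 * ((spec.band_centers - noise.lidar_peak_center) / sigma) ** 2
    )


def _quantize(values: np.ndarray, spec: CameraSpec) -> np.ndarray:
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return np.clip(np.rint(values), 0, spec.full_scale).astype(dtype)


def _add_noise(signal: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = signal
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, signal.shape)
    if noise.shot_noise_scale > 0:
        out = out + rng.standard_normal(signal.shape) * (noise.shot_noise_scale * signal)
    return out


def simulate_snapshot_capture(
    scene: PhantomScene,
    camera_spec: CameraSpec | None = None,
    noise_model: NoiseModel | None = None,
    crosstalk_matrix: np.ndarray | None = None,
) -> CaptureSet:
    """Simulate a full-sensor snapshot mosaic frame plus references.

    Sensor pixel ``(r, c)`` in the active filter zone samples band
    ``5*(r mod 5) + (c mod 5)`` of the crosstalk-mixed, Gaussian-band-
    integrated scene radiance at the spatial tile ``(r // 5, c // 5)``;
    scene pixels are block-averaged down to the snapshot's coarser spatial
    grid first.  The laser peak is added to the raw capture only.  The
    white reference images a unit-reflectance flat target under the same
    geometry; the dark reference is read noise on the dark level.
    """
    spec = camera_spec if camera_spec is not None else snapshot_camera()
    noise = noise_model if noise_model is not None else default_snapshot_noise()
    if spec.name != "snapshot":
        raise ValueError("camera_spec must be a snapshot camera")
    m = spec.mosaic_size
    active_r = spec.sensor_rows - spec.crop_rows
    active_c = spec.sensor_cols - spec.crop_cols
    if active_r % m or active_c % m:
        raise GeometryError("active filter zone not divisible by the mosaic size")
    cr, cc = active_r // m, active_c // m
    if scene.height % cr or scene.width % cc:
        raise GeometryError(
            f"scene {scene.height}x{scene.width} does not cover the "
            f"{cr}x{cc} snapshot field of view by an integer factor"
        )
    rat_r, rat_c = scene.height // cr, scene.width // cc

    if crosstalk_matrix is None:
        crosstalk_matrix = default_crosstalk_matrix(spec.n_bands)
    x = np.asarray(crosstalk_matrix, dtype=float)
    if x.shape != (spec.n_bands, spec.n_bands):
        raise ShapeError("crosstalk matrix must be bands x bands")
    if not np.allclose(x.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("crosstalk matrix rows must sum to 1")

    # block-average scene reflectance to the snapshot spatial grid
    block = scene.reflectance.reshape(cr, rat_r, cc, rat_c, -1).mean(axis=(1, 3))
    w = band_response_matrix(scene.wavelength_grid, spec.band_centers, spec.band_fwhm)
    r_bands = block @ w          # (cr, cc, bands)
    r_mixed = r_bands @ x

    gain = noise.white_fill * spec.full_scale - noise.dark_level
    bump = _lidar_bump(spec, noise)
    raw_sig = noise.dark_level + gain * r_mixed + bump[None, None, :]
    white_sig = np.full_like(raw_sig, noise.dark_level + gain)
    dark_sig = np.full_like(raw_sig, noise.dark_level)

    rng = np.random.default_rng(noise.seed)
    frames = []
    for sig in (raw_sig, white_sig, dark_sig):
        from .preprocess import remosaic

        frame = remosaic(sig, m)  # (active_r, active_c), band b at (m*y+b//m, m*x+b%m)
        # the unfiltered border outside the active filter zone still sees
        # light; replicate the edge response there
        full = np.pad(frame, ((0, spec.crop_rows), (0, spec.crop_cols)), mode="edge")
        frames.append(_quantize(_add_noise(full, noise, rng), spec))
    return CaptureSet(i_raw=frames[0], i_white=frames[1], i_dark=frames[2], camera=spec)


def simulate_linescan_capture(
    scene: PhantomScene,
    camera_spec: CameraSpec | None = None,
    noise_model: NoiseModel | None = None,
    n_lines: int | None = None,
) -> CaptureSet:
    """Simulate a pushbroom scan: a stack of 16-bit spectral lines.

    Scene column ``i`` becomes line ``i``; each line is
    ``line_length x bands``.  The returned stacks have shape
    ``(n_lines, line_length, bands)``.  No laser peak is added (the
    rangefinder is off while the linescan camera scans).
    """
    spec = camera_spec if camera_spec is not None else linescan_camera(line_length=scene.height)
    noise = noise_model if noise_model is not None else default_linescan_noise()
    if spec.name != "linescan":
        raise ValueError("camera_spec must be a linescan camera")
    if n_lines is None:
        n_lines = scene.width
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if spec.line_length != scene.height:
        raise GeometryError(
            f"line_length {spec.line_length} != scene height {scene.height}"
        )
    if n_lines > scene.width:
        raise GeometryError(f"cannot scan {n_lines} lines from a {scene.width}-wide scene")

    w = band_response_matrix(scene.wavelength_grid, spec.band_centers, spec.band_fwhm)
    # (height, n_lines, bands) -> (n_lines, height, bands)
    r_bands = np.einsum("hwl,lb->whb", scene.reflectance[:, :n_lines, :], w)

    gain = noise.white_fill * spec.full_scale - noise.dark_level
    raw_sig = noise.dark_level + gain * r_bands
    white_sig = np.full_like(raw_sig, noise.dark_level + gain)
    dark_sig = np.full_like(raw_sig, noise.dark_level)

    rng = np.random.default_rng(noise.seed)
    stacks = [
        _quantize(_add_noise(sig, noise, rng), spec)
        for sig in (raw_sig, white_sig, dark_sig)
    ]
    return CaptureSet(i_raw=stacks[0], i_white=stacks[1], i_dark=stacks[2], camera=spec)


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

def make_roi_masks(scene: PhantomScene, roi_size: int = 5) -> RoiMasks:
    """Per-tissue ROI pixel lists for both cameras.

    Snapshot ROIs are exactly ``roi_size x roi_size`` pixel squares (in
    snapshot-cube coordinates) centered on each tissue disk; linescan ROIs
    are the same physical squares at the scene's full resolution, i.e.
    ``(roi_size * ratio)^2`` pixels, from which 25 pixels are later drawn
    at random for a fair comparison.
    """
    if roi_size < 1:
        raise ValueError("roi_size must be >= 1")
    geom = scene.geometry
    ratio = geom.snapshot_ratio
    half_diag = (roi_size * ratio / 2.0) * math.sqrt(2.0)
    if half_diag > geom.disk_radius:
        raise GeometryError(
            f"a {roi_size}x{roi_size} snapshot ROI (x{ratio} resolution ratio) "
            f"does not fit inside a radius-{geom.disk_radius} ring interior"
        )
    snapshot: dict[str, list[tuple[int, int]]] = {}
    linescan: dict[str, list[tuple[int, int]]] = {}
    centers = {"healthy": geom.healthy_center, "pathological": geom.pathological_center}
    for tissue, center in centers.items():
        sr, sc = center[0] // ratio, center[1] // ratio
        lo = roi_size // 2
        snapshot[tissue] = [
            (sr - lo + i, sc - lo + j) for i in range(roi_size) for j in range(roi_size)
        ]
        side = roi_size * ratio
        r0, c0 = center[0] - side // 2, center[1] - side // 2
        linescan[tissue] = [
            (r0 + i, c0 + j) for i in range(side) for j in range(side)
        ]
    return RoiMasks(snapshot=snapshot, linescan=linescan,
                    roi_size=roi_size, snapshot_ratio=ratio)
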