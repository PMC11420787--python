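"""Minimal ENVI image reader/writer (.hdr text header + flat binary).

Supports the BSQ / BIL / BIP interleaves, the common numeric data types,
and the ``wavelength`` header list, which this package requires (a cube
without its wavelength grid is useless downstream).  Headers are written
with full-precision wavelengths; reading back a written cube is
bit-identical.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .cube import HyperCube
from .errors import MetadataError, SizeMismatchError

__all__ = ["read_envi_cube", "write_envi_cube"]

# ENVI data-type codes <-> numpy dtypes
_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32,
}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in (".hdr", ".raw", ".img"):
        p = p.with_suffix("")
    return p.with_suffix(".hdr"), p.with_suffix(".raw")


def write_envi_cube(
    cube: HyperCube,
    path: str | Path,
    interleave: str = "bil",
    dtype: str = "float32",
    force: bool = False,
) -> tuple[Path, Path]:
    """Write ``<path>.hdr`` + ``<path>.raw``; refuses to overwrite without force."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"interleave must be bsq/bil/bip, got {interleave!r}")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _CODES:
        raise ValueError(f"unsupported dtype {dtype!r}")
    hdr_path, raw_path = _paths(path)
    if not force and (hdr_path.exists() or raw_path.exists()):
        raise FileExistsError(f"{hdr_path} or {raw_path} exists; pass force=True")

    data = cube.data.astype(np_dtype)
    rows, cols, bands = data.shape
    if interleave == "bip":      # (lines, samples, bands)
        payload = data
    elif interleave == "bil":    # (lines, bands, samples)
        payload = data.transpose(0, 2, 1)
    else:                        # bsq: (bands, lines, samples)
        payload = data.transpose(2, 0, 1)
    raw_path.write_bytes(np.ascontiguousarray(payload).tobytes())

    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {hscompare hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODES[np_dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    return hdr_path, raw_path


def _parse_header(text: str) -> dict:
    # fold {...} blocks onto one line, then parse key = value pairs
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(path: str | Path) -> HyperCube:
    """Read an ENVI cube; wavelengths are parsed from the header.

    Raises :class:`MetadataError` when the wavelength list is missing and
    :class:`SizeMismatchError` when the binary payload does not match the
    header geometry.
    """
    hdr_path, raw_path = _paths(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise MetadataError(f"header {hdr_path} missing field {exc}") from None
    if "wavelength" not in fields:
        raise MetadataError(f"header {hdr_path} has no wavelength list")
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if wavelengths.size != bands:
        raise MetadataError(
            f"{wavelengths.size} wavelengths for {bands} bands in {hdr_path}"
        )
    if code not in _DTYPES:
        raise MetadataError(f"unsupported ENVI data type code {code}")
    np_dtype = np.dtype(_DTYPES[code])

    payload = np.frombuffer(raw_path.read_bytes(), dtype=np_dtype)
    expected = rows * cols * bands
    if payload.size != expected:
        raise SizeMismatchError(
            f"{raw_path}: {payload.size} values, header implies {expected}"
        )
    if interleave == "bip":
        data = payload.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = payload.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = payload.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise MetadataError(f"unknown interleave {interleave!r}")
    return HyperCube(data.copy(), wavelengths)
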