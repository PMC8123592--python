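"""ENVI hypercube I/O and empirical-line reflectance calibration.

ENVI stores a cube as a flat binary file plus a small text header. We emit
``data type = 4`` (float32), ``byte order = 0`` and a ``wavelength`` block in
nm, and accept any of the three standard interleaves (BIL/BIP/BSQ) on read.

Calibration follows the empirical line method of line-scan (pushbroom)
practice: dark and white reference frames are averaged to a single
columns x bands line, broadcast along the scan axis, and

    reflectance = (specimen - dark) / (white - dark)

per pixel and band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import WavelengthGrid

log = logging.getLogger(__name__)

_DTYPE_CODES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_CODE_FOR_DTYPE = {np.dtype(v): k for k, v in _DTYPE_CODES.items()}

DEFAULT_CLIP = (-0.05, 1.5)


@dataclass
class Hypercube:
    """Reflectance (or radiance) cube: rows x cols x bands with its grid."""

    data: np.ndarray
    grid: WavelengthGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {len(self.grid)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_image(self, wavelength_nm: float) -> np.ndarray:
        """The single-band image at the grid band nearest ``wavelength_nm``."""
        return self.data[:, :, self.grid.index_of(wavelength_nm)]


@dataclass
class RawCapture:
    """Encoded-radiance specimen cube with its dark/white reference frames.

    Reference frames are line captures: (n_frames, cols, bands).
    """

    specimen: np.ndarray
    dark_frames: np.ndarray
    white_frames: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        bands = len(self.grid)
        if self.specimen.shape[2] != bands:
            raise ValueError("specimen band count does not match grid")
        for name in ("dark_frames", "white_frames"):
            frames = getattr(self, name)
            if frames.ndim != 3:
                raise ValueError(f"{name} must be (n_frames, cols, bands)")
            if frames.shape[1:] != self.specimen.shape[1:]:
                raise ValueError(
                    f"{name} shape {frames.shape[1:]} does not match specimen "
                    f"columns/bands {self.specimen.shape[1:]}"
                )


# ---------------------------------------------------------------------------
# ENVI read/write


def _format_header(cube: Hypercube, interleave: str) -> str:
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.grid.centers)
    lines = [
        "ENVI",
        "description = {hemospec synthetic hypercube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODE_FOR_DTYPE[np.dtype(cube.data.dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
    ]
    return "\n".join(lines) + "\n"


def write_envi(cube: Hypercube, header_path, data_path=None, interleave: str = "bil") -> None:
    """Write a cube as ENVI header + flat binary in the given interleave."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    data_path = Path(data_path) if data_path else header_path.with_suffix(".dat")
    arr = np.ascontiguousarray(cube.data)
    if interleave == "bip":
        out = arr  # (lines, samples, bands)
    elif interleave == "bil":
        out = arr.transpose(0, 2, 1)  # (lines, bands, samples)
    else:
        out = arr.transpose(2, 0, 1)  # (bands, lines, samples)
    header_path.write_text(_format_header(cube, interleave))
    np.ascontiguousarray(out).tofile(data_path)


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    key, buf, in_block = None, [], False
    for line in text.splitlines()[1:]:
        if in_block:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_block = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if value.startswith("{") and "}" not in value:
            buf, in_block = [value], True
        else:
            fields[key] = value
    return fields


def read_envi(header_path, data_path=None) -> Hypercube:
    """Read an ENVI cube; the header's wavelength block becomes the grid."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required key: {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required key: 'wavelength'")
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("only little-endian (byte order = 0) files are supported")

    wl_text = fields["wavelength"].strip().strip("{}")
    centers = np.array([float(tok) for tok in wl_text.replace(",", " ").split()])
    if centers.size != bands:
        raise ValueError(
            f"wavelength block has {centers.size} entries but header declares {bands} bands"
        )
    grid = WavelengthGrid(centers)

    data_path = Path(data_path) if data_path else header_path.with_suffix(".dat")
    dtype = np.dtype(_DTYPE_CODES[dtype_code])
    expected = rows * cols * bands
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != expected:
        raise ValueError(
            f"data file holds {raw.size} values, header implies {expected} "
            f"({rows} x {cols} x {bands})"
        )
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    offset = int(fields.get("header offset", "0"))
    meta = {"interleave": interleave, "header offset": offset}
    return Hypercube(data=np.ascontiguousarray(data), grid=grid, metadata=meta)


# ---------------------------------------------------------------------------
# calibration


def average_reference(frames: np.ndarray) -> np.ndarray:
    """Per-pixel, per-band arithmetic mean of reference line frames."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need at least one (cols, bands) reference frame")
    return frames.mean(axis=0)


def calibrate_reflectance(
    raw: RawCapture, clip: tuple[float, float] | None = DEFAULT_CLIP
) -> Hypercube:
    """Empirical-line calibration: (specimen - dark) / (white - dark).

    The averaged references (one columns x bands line each) are broadcast
    along the scan axis. A zero denominator at any column/band is an error;
    out-of-range reflectances are clipped to ``clip`` and counted.
    """
    dark = average_reference(raw.dark_frames)
    white = average_reference(raw.white_frames)
    denom = white - dark
    bad = np.argwhere(denom == 0)
    if bad.size:
        listed = ", ".join(f"(col {c}, band {b})" for c, b in bad[:5])
        raise ValueError(
            f"white - dark is zero at {bad.shape[0]} column/band positions: {listed}"
        )
    reflectance = (raw.specimen.astype(np.float64) - dark[None]) / denom[None]
    n_clipped = 0
    if clip is not None:
        lo, hi = clip
        n_clipped = int(np.sum((reflectance < lo) | (reflectance > hi)))
        if n_clipped:
            log.warning("clipped %d reflectance values outside [%g, %g]", n_clipped, lo, hi)
        reflectance = np.clip(reflectance, lo, hi)
    return Hypercube(
        data=reflectance.astype(np.float32),
        grid=raw.grid,
        metadata={"calibration": "empirical_line", "n_clipped": n_clipped},
    )
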