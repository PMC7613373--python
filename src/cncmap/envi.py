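"""Minimal ENVI cube reader/writer (BSQ/BIL/BIP, text header + flat binary).

Supports the subset of the ENVI header dialect the retrieval pipeline needs:
``samples/lines/bands``, ``data type`` (IEEE float32/float64, common ints),
``interleave``, ``byte order`` and the ``wavelength`` / ``fwhm`` arrays
required for spectral subsetting.  This is intentionally small; it is not a
general geospatial raster library and carries no map projection handling.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .bands import BandGrid

__all__ = ["read_envi", "write_envi"]

_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4"}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header")
    # join multi-line { ... } blocks, then parse key = value
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in body.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def _parse_array(val: str) -> np.ndarray:
    return np.array([float(x) for x in val.strip("{} ").split(",") if x.strip()])


def read_envi(header_path) -> tuple[np.ndarray, BandGrid | None, dict]:
    """Read an ENVI cube; returns (values[rows, cols, bands], grid, header).

    ``grid`` is None when the header lacks wavelength/fwhm arrays.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields.get("interleave", "bsq").lower()
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(_DTYPES[code]).newbyteorder("<" if byte_order == 0 else ">")

    data_path = header_path.with_suffix("")
    if not data_path.exists():
        data_path = header_path.with_suffix(".img")
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError("ENVI data size mismatches header dimensions")
    if interleave == "bsq":
        cube = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    grid = None
    if "wavelength" in fields and "fwhm" in fields:
        grid = BandGrid(_parse_array(fields["wavelength"]), _parse_array(fields["fwhm"]))
    return np.ascontiguousarray(cube, dtype=float), grid, fields


def write_envi(
    path_prefix, values: np.ndarray, grid: BandGrid | None = None, interleave: str = "bsq"
) -> Path:
    """Write (rows, cols, bands) values as float32 ENVI; returns header path."""
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[:, :, None]
    rows, cols, bands = values.shape
    data = values.astype("<f4")
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = data
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    prefix = Path(path_prefix)
    data_path = prefix.with_suffix(".img")
    flat.tofile(data_path)
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype('f4')]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if grid is not None:
        lines.append("wavelength units = Nanometers")
        lines.append("wavelength = {" + ", ".join(f"{c:.3f}" for c in grid.centers) + "}")
        lines.append("fwhm = {" + ", ".join(f"{w:.3f}" for w in grid.fwhm) + "}")
    header_path = prefix.with_suffix(".hdr")
    header_path.write_text("\n".join(lines) + "\n")
    return header_path
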