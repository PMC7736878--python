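"""Minimal ENVI cube reader/writer (text header + raw binary).

Supports BIL, BSQ and BIP interleaves, the common float/integer data
types and both byte orders. The units tag, pixel pitch and free-form
metadata ride along in the header so cubes round-trip losslessly;
validity masks are written as single-band ENVI rasters (nonzero =
valid).
"""

from __future__ import annotations

import os
import re

import numpy as np

from .cube import SpectralCube

_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
           5: np.float64, 12: np.uint16, 13: np.uint32}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bil", "bsq", "bip")


def _parse_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values before splitting into fields
    body = text.split("\n", 1)[1]
    for match in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                             body, flags=re.MULTILINE | re.DOTALL):
        key = match.group(1).strip().lower()
        value = match.group(2).strip()
        fields[key] = value
    return fields


def _parse_list(value: str) -> list[str]:
    return [v.strip() for v in value.strip("{}").split(",") if v.strip()]


def read_envi(header_path: str) -> SpectralCube:
    """Read an ENVI header + binary pair into a :class:`SpectralCube`.

    The header must carry a wavelength block; the binary file size must
    match the declared dimensions exactly.
    """
    with open(header_path) as fh:
        fields = _parse_header(fh.read())
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field {key!r}")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    interleave = fields["interleave"].lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    wavelengths = np.array([float(v) for v in _parse_list(fields["wavelength"])])
    if wavelengths.size != bands:
        raise ValueError("wavelength count does not match band count")

    dtype = np.dtype(_DTYPES[code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    binary_path = _sibling_binary(header_path)
    raw = np.fromfile(binary_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"binary holds {raw.size} values, header declares {expected}")
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    units = fields.get("units", "DN").strip()
    pitch = float(fields.get("pixel pitch mm", "1.0"))
    return SpectralCube(np.ascontiguousarray(data, dtype=float), wavelengths,
                        units=units, pixel_pitch=pitch,
                        meta={"header": header_path})


def _sibling_binary(header_path: str) -> str:
    base = header_path[:-4] if header_path.endswith(".hdr") else header_path
    for candidate in (base, base + ".img", base + ".dat", base + ".raw"):
        if os.path.exists(candidate) and not candidate.endswith(".hdr"):
            return candidate
    raise FileNotFoundError(f"no binary file found next to {header_path}")


def write_envi(cube: SpectralCube, path: str, interleave: str = "bil",
               dtype=np.float64) -> tuple[str, str]:
    """Write a cube as ENVI header + raw binary; returns (header, binary).

    *path* is the binary path; the header is written next to it with a
    ``.hdr`` suffix. The units tag and pixel pitch are preserved as
    header metadata.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    lines, samples, bands = cube.shape
    data = cube.data.astype(dtype)
    if interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    elif interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    else:
        ordered = data
    ordered.tofile(path)

    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)  # exact round-trip
    header_path = path + ".hdr"
    with open(header_path, "w") as fh:
        fh.write(
            "ENVI\n"
            "description = {icealgae spectral cube}\n"
            f"samples = {samples}\n"
            f"lines = {lines}\n"
            f"bands = {bands}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            f"data type = {_DTYPE_CODES[dtype]}\n"
            f"interleave = {interleave}\n"
            "byte order = 0\n"
            f"units = {cube.units}\n"
            f"pixel pitch mm = {cube.pixel_pitch:.6g}\n"
            f"wavelength units = Nanometers\n"
            f"wavelength = {{{wl}}}\n"
        )
    return header_path, path


def write_raster(grid: np.ndarray, path: str) -> tuple[str, str]:
    """Write a single-band raster (mask, score map, index map) as ENVI."""
    cube = SpectralCube(np.asarray(grid, dtype=float)[:, :, None],
                        np.array([0.0]), units="DN")
    # single-band rasters carry a placeholder wavelength of 0 nm
    return write_envi(cube, path, interleave="bsq")
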