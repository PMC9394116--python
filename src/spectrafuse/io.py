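"""Readers for the raw-image inputs of the extraction path.

Hyperspectral line-scan systems commonly store cubes in the ENVI layout:
a small text header (``.hdr``) next to a flat binary file, with the cube
interleaved band-sequential (BSQ), band-interleaved-by-line (BIL) or
band-interleaved-by-pixel (BIP).  ``read_envi`` covers exactly that
subset.  ROI masks are read from plain text/CSV (nonzero = inside) or any
image format PIL/imageio already handles, via ``read_mask``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}


def read_envi_header(hdr_path: str | Path) -> dict:
    """Parse an ENVI text header into a {lowercase key: value} dict."""
    text = Path(hdr_path).read_text()
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if "=" in line and key is None:
            k, v = line.split("=", 1)
            k, v = k.strip().lower(), v.strip()
            if v.startswith("{") and not v.endswith("}"):
                key, buf = k, v
            else:
                fields[k] = v.strip("{}").strip()
        elif key is not None:
            buf += " " + line
            if line.endswith("}"):
                fields[key] = buf.strip("{}").strip()
                key, buf = None, ""
    return fields


def read_envi(hdr_path: str | Path, data_path: str | Path | None = None) -> np.ndarray:
    """Read an ENVI cube as a (lines, samples, bands) float array.

    ``data_path`` defaults to the header path with its ``.hdr`` suffix
    stripped (or swapped for ``.dat``/``.img`` if that file exists).
    """
    hdr_path = Path(hdr_path)
    hdr = read_envi_header(hdr_path)
    lines = int(hdr["lines"])
    samples = int(hdr["samples"])
    bands = int(hdr["bands"])
    dtype = _ENVI_DTYPES[int(hdr["data type"])]
    interleave = hdr.get("interleave", "bsq").lower()
    byte_order = int(hdr.get("byte order", 0))
    offset = int(hdr.get("header offset", 0))

    if data_path is None:
        stem = hdr_path.with_suffix("")
        for cand in (stem, stem.with_suffix(".dat"), stem.with_suffix(".img")):
            if cand.exists() and cand != hdr_path:
                data_path = cand
                break
        else:
            raise FileNotFoundError(f"no data file found next to {hdr_path}")

    data = np.fromfile(data_path, dtype=dtype, offset=offset, count=lines * samples * bands)
    if byte_order == 1:
        data = data.byteswap()
    if interleave == "bsq":
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = data.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return cube.astype(float)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a boolean ROI mask from CSV/TSV/TXT or an image file."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv", ".txt"):
        delim = "," if path.suffix.lower() == ".csv" else None
        arr = np.loadtxt(path, delimiter=delim)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
    return np.asarray(arr) != 0
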