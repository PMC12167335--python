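"""Minimal ENVI image I/O (text ``.hdr`` header plus raw binary cube).

Supports the interleaves (BSQ/BIL/BIP) and the floating point / integer
data types that hyperspectral snapshot cameras commonly emit.  The
``wavelength`` header field carries band centers in nanometres.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

# ENVI "data type" codes <-> numpy dtypes
_DTYPE_TO_CODE = {
    np.dtype("uint8"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


def write_envi(path_hdr: str | Path, data: np.ndarray,
               band_centers_nm: np.ndarray | None = None,
               interleave: str = "bsq") -> None:
    """Write ``data`` (rows x cols x bands) as an ENVI header + raw pair.

    ``path_hdr`` must end in ``.hdr``; the binary goes next to it with the
    ``.raw`` extension.
    """
    path_hdr = Path(path_hdr)
    if path_hdr.suffix != ".hdr":
        raise ValueError(f"header path must end in .hdr, got {path_hdr}")
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("expected a rows x cols x bands array")
    lines, samples, bands = data.shape
    dtype = data.dtype
    if dtype not in _DTYPE_TO_CODE:
        data = data.astype(np.float64)
        dtype = data.dtype

    if interleave == "bsq":
        ordered = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        ordered = np.transpose(data, (0, 2, 1))
    else:  # bip
        ordered = data

    lines_out = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_CODE[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if band_centers_nm is not None:
        wl = np.asarray(band_centers_nm, dtype=float)
        if wl.shape != (bands,):
            raise ValueError("band_centers_nm length must equal band count")
        lines_out.append("wavelength units = Nanometers")
        lines_out.append(
            "wavelength = { " + ", ".join(f"{w:.6f}" for w in wl) + " }")
    path_hdr.write_text("\n".join(lines_out) + "\n")
    ordered.astype(dtype.newbyteorder("<")).tofile(path_hdr.with_suffix(".raw"))


def _parse_header(text: str) -> dict:
    # collapse { ... } blocks onto single lines before splitting on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path_hdr: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI pair; returns ``(data rows x cols x bands, band_centers_nm or None)``."""
    path_hdr = Path(path_hdr)
    fields = _parse_header(path_hdr.read_text())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields.get("interleave", "bsq").lower()
    byte_order = int(fields.get("byte order", "0"))
    if code not in _CODE_TO_DTYPE:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = _CODE_TO_DTYPE[code].newbyteorder("<" if byte_order == 0 else ">")

    raw_path = path_hdr.with_suffix(".raw")
    if not raw_path.exists():  # some writers use .img or no extension
        for ext in (".img", ".dat", ""):
            cand = path_hdr.with_suffix(ext)
            if cand.exists() and cand != path_hdr:
                raw_path = cand
                break
    flat = np.fromfile(raw_path, dtype=dtype)
    if flat.size != samples * lines * bands:
        raise ValueError("binary size does not match header dimensions")
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    wavelengths = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = np.array(
            [float(tok) for tok in inner.split(",") if tok.strip()], dtype=float)
        if wavelengths.shape != (bands,):
            raise ValueError("wavelength list length does not match band count")
    return np.ascontiguousarray(data), wavelengths
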