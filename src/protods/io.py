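"""Cube and manifest I/O.

Two on-disk cube formats are supported:

* ENVI: a plain-text ``.hdr`` header next to a raw binary file, band-sequential
  (BSQ) float32 or float64.  Only the header keys needed for round-tripping are
  written (samples/lines/bands, data type, interleave, byte order, wavelength).
* ``.npz`` array container: a single numpy archive with ``values`` (H x W x B)
  and ``wavelengths`` arrays.

Instance manifests are CSV files with columns ``instance_id, label, cube_path``.
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .cube import RawCube
from .errors import FormatError

__all__ = ["load_cube", "write_cube", "read_manifest", "write_manifest"]

# ENVI data type codes for the float dtypes we emit
_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _header_path(path: str) -> str:
    return path + ".hdr" if not path.endswith(".hdr") else path


def write_cube(cube: RawCube, path: str, dtype=np.float64) -> None:
    """Write a cube to ``path`` as ENVI (``.hdr`` + raw BSQ) or ``.npz``."""
    if path.endswith(".npz"):
        np.savez(path, values=cube.values, wavelengths=cube.wavelengths)
        return
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise FormatError(f"unsupported ENVI dtype {dtype}")
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.6f}" for x in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(_header_path(path), "w") as fh:
        fh.write(header)
    # BSQ: band-sequential, each band an H x W plane
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0)).astype(
        dtype.newbyteorder("<")
    ).tofile(path)


def _parse_envi_header(hdr_path: str) -> dict:
    try:
        with open(hdr_path) as fh:
            text = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read ENVI header {hdr_path!r}: {exc}") from exc
    if not text.lstrip().startswith("ENVI"):
        raise FormatError(f"{hdr_path!r} is not an ENVI header")
    fields: dict = {}
    # key = value, where value may be a { ... } block spanning lines
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", text, re.M):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = [v.strip() for v in val.strip("{}").split(",") if v.strip()]
        fields[key] = val
    return fields


def load_cube(path: str) -> RawCube:
    """Load a cube written by :func:`write_cube` (ENVI or ``.npz``)."""
    if path.endswith(".npz"):
        try:
            with np.load(path) as archive:
                if "wavelengths" not in archive:
                    raise FormatError(f"{path!r}: missing wavelength metadata")
                if "values" not in archive:
                    raise FormatError(f"{path!r}: missing values array")
                return RawCube(
                    values=archive["values"], wavelengths=archive["wavelengths"]
                )
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"cannot read array container {path!r}: {exc}") from exc
    hdr = _parse_envi_header(_header_path(path))
    try:
        w = int(hdr["samples"])
        h = int(hdr["lines"])
        b = int(hdr["bands"])
        code = int(hdr["data type"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed ENVI header for {path!r}: {exc}") from exc
    if "wavelength" not in hdr:
        raise FormatError(f"{path!r}: ENVI header has no wavelength metadata")
    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise FormatError(f"{path!r}: only BSQ interleave is supported")
    if code not in _ENVI_DTYPES:
        raise FormatError(f"{path!r}: unsupported ENVI data type {code}")
    wavelengths = np.array([float(x) for x in hdr["wavelength"]])
    if not os.path.exists(path):
        raise FormatError(f"raw data file {path!r} not found")
    data = np.fromfile(path, dtype=np.dtype(_ENVI_DTYPES[code]).newbyteorder("<"))
    if data.size != h * w * b:
        raise FormatError(
            f"{path!r}: expected {h * w * b} values ({h}x{w}x{b}), found {data.size}"
        )
    values = np.moveaxis(data.reshape(b, h, w), 0, 2)
    return RawCube(values=values, wavelengths=wavelengths)


def read_manifest(path: str) -> pd.DataFrame:
    """Read an instance manifest CSV (instance_id, label, cube_path)."""
    try:
        df = pd.read_csv(path, dtype={"instance_id": str})
    except Exception as exc:
        raise FormatError(f"cannot read manifest {path!r}: {exc}") from exc
    missing = {"instance_id", "label", "cube_path"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path!r} lacks columns: {sorted(missing)}")
    df["label"] = df["label"].astype(int)
    return df


def write_manifest(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)
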