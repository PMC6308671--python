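"""Minimal ENVI reader/writer: text ``.hdr`` plus BIL-interleaved float32.

Only the subset needed here is supported: ``interleave = bil``,
``data type = 4`` (float32), byte order 0, with a wavelength list in the
header.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .datatypes import Hypercube


def write_envi(path_stem: str, cube: Hypercube) -> None:
    """Write ``<stem>.hdr`` and ``<stem>.bil``."""
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.3f}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {{{cube.instrument or 'hsifuse cube'}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(path_stem + ".hdr", "w") as fh:
        fh.write(hdr)
    # BIL: line-major, then band, then sample
    data = np.ascontiguousarray(
        np.transpose(cube.values, (0, 2, 1)).astype("<f4"))
    data.tofile(path_stem + ".bil")


def _parse_header(text: str) -> dict:
    fields = {}
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path_stem: str) -> Hypercube:
    """Read a cube written by :func:`write_envi` (``.hdr`` + ``.bil``)."""
    hdr_path = path_stem + ".hdr"
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    if fields.get("interleave", "bil").lower() != "bil":
        raise ValueError("only BIL interleave is supported")
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (data type 4) is supported")
    wl_text = fields.get("wavelength", "")
    wl = np.array([float(v) for v in wl_text.strip("{} ").split(",") if v.strip()])
    if len(wl) != bands:
        raise ValueError("wavelength list length does not match band count")
    bil_path = path_stem + ".bil"
    if not os.path.exists(bil_path):
        raise FileNotFoundError(bil_path)
    data = np.fromfile(bil_path, dtype="<f4")
    if data.size != rows * cols * bands:
        raise ValueError("binary size does not match header dimensions")
    values = np.transpose(data.reshape(rows, bands, cols), (0, 2, 1))
    desc = fields.get("description", "").strip("{} ")
    return Hypercube(values.astype(float), wl, desc)
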