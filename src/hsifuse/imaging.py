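"""Cube-level preprocessing: reflectance calibration, masking, sepal
exclusion, mean-spectrum extraction and spectral-range trimming."""

from __future__ import annotations

import warnings

import numpy as np
from skimage import measure

from .datatypes import Hypercube, PixelMask, SpectrumTable

DENOM_FLOOR = 1e-12


def calibrate(raw: Hypercube, white: Hypercube, dark: Hypercube) -> Hypercube:
    """Flat-field calibration: (raw - dark) / (white - dark), elementwise."""
    for other, name in ((white, "white"), (dark, "dark")):
        if other.shape != raw.shape:
            raise ValueError(f"{name} cube shape {other.shape} != raw {raw.shape}")
        if not np.array_equal(other.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} cube wavelength axis differs from raw")
    denom = white.values - dark.values
    bad = np.abs(denom) < DENOM_FLOOR
    if np.any(bad):
        r, c, b = np.unravel_index(int(np.argmax(bad)), bad.shape)
        raise ValueError(
            f"white == dark at pixel ({r}, {c}), band "
            f"{raw.wavelengths[b]:.1f} nm: calibration undefined"
        )
    return Hypercube((raw.values - dark.values) / denom, raw.wavelengths.copy(),
                     raw.instrument)


def make_mask(cube: Hypercube, band_nm: float, threshold: float,
              min_area: int = 50) -> PixelMask:
    """Threshold the nearest single-band image and drop small components.

    "Erosion" of small clutter is implemented as 8-connected
    component-area filtering, matching its stated purpose.
    """
    img = cube.band_image(band_nm)
    fg = img > threshold
    labels = measure.label(fg, connectivity=2)
    if min_area > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        drop = np.nonzero(counts < min_area)[0]
        if len(drop):
            labels[np.isin(labels, drop)] = 0
    # relabel 1..k consecutively
    labels = measure.label(labels > 0, connectivity=2)
    fg = labels > 0
    if not fg.any():
        warnings.warn("mask is empty: no pixel passed the threshold",
                      stacklevel=2)
    return PixelMask(fg, labels)


def exclude_sepals(cube: Hypercube, mask: PixelMask,
                   ratio_threshold: float = 1.2,
                   num_nm: float = 1200.0, den_nm: float = 1075.0) -> PixelMask:
    """Remove pixels whose band(1200)/band(1075) ratio exceeds the threshold."""
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    num = cube.band_image(num_nm)
    den = cube.band_image(den_nm)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.abs(den) > DENOM_FLOOR, num / den, np.inf)
    keep = mask.mask & ~(ratio > ratio_threshold)
    labels = measure.label(keep, connectivity=2)
    return PixelMask(keep, labels)


def mean_spectrum(cube: Hypercube, mask: PixelMask) -> SpectrumTable:
    """One row per labeled object: per-band arithmetic mean over its pixels."""
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    n_obj = mask.n_objects
    if n_obj < 1:
        raise ValueError("mask has no labeled objects")
    rows = np.zeros((n_obj, cube.shape[2]))
    for k in range(1, n_obj + 1):
        sel = mask.object_labels == k
        if not sel.any():
            raise ValueError(f"object {k} has no pixels")
        rows[k - 1] = cube.values[sel].mean(axis=0)
    ids = [f"obj{k}" for k in range(1, n_obj + 1)]
    return SpectrumTable(rows, cube.wavelengths.copy(), ids)


def trim_range(table: SpectrumTable, lo: float, hi: float) -> SpectrumTable:
    """Keep columns with lo <= wavelength <= hi, preserving order."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    keep = np.nonzero((table.wavelengths >= lo) & (table.wavelengths <= hi))[0]
    if len(keep) == 0:
        raise ValueError(f"no wavelengths survive trimming to [{lo}, {hi}] nm")
    return table.select_columns(keep)
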