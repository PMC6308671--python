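"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* class labels are encoded ``+1`` (healthy) and ``-1`` (bruised);
* a :class:`SpectrumTable` holds one mean-reflectance spectrum per sample
  (rows) over a wavelength grid (columns);
* column names carry an optional instrument namespace (``"PB:850.8"``) so
  that tables from different instruments can be concatenated without
  wavelength collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEALTHY = 1
BRUISED = -1

LABEL_NAMES = {HEALTHY: "healthy", BRUISED: "bruised"}
LABEL_CODES = {"healthy": HEALTHY, "bruised": BRUISED}


def _as_float_array(x, ndim):
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"expected {ndim}-d array, got {arr.ndim}-d")
    return arr


@dataclass
class SpectrumTable:
    """Samples x wavelengths mean-reflectance matrix with optional labels.

    Parameters
    ----------
    values : (n_samples, n_bands) float array
        Mean reflectance per sample and band.
    wavelengths : (n_bands,) float array
        Band centers in nm.  Strictly increasing unless the table is the
        result of a cross-instrument concatenation (``fused=True``).
    sample_ids : list of str
    labels : optional (n_samples,) int array of +1 / -1
    columns : optional list of str
        Column names; defaults to the wavelengths formatted with one
        decimal.  Fused tables use instrument-namespaced names.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list
    labels: np.ndarray | None = None
    columns: list = field(default=None)
    fused: bool = False

    def __post_init__(self):
        self.values = _as_float_array(self.values, 2)
        self.wavelengths = _as_float_array(self.wavelengths, 1)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match rows")
        if len(self.wavelengths) != p:
            raise ValueError("wavelength axis does not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum table contains non-finite values")
        if not self.fused and p > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.columns is None:
            self.columns = [f"{w:.1f}" for w in self.wavelengths]
        self.columns = [str(c) for c in self.columns]
        if len(self.columns) != p:
            raise ValueError("column names do not match columns")
        if len(set(self.columns)) != p:
            raise ValueError("duplicate column names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match rows")
            bad = set(np.unique(self.labels)) - {HEALTHY, BRUISED}
            if bad:
                raise ValueError(f"labels must be +1/-1, got extra {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def select_columns(self, idx) -> "SpectrumTable":
        idx = np.asarray(idx, dtype=int)
        return SpectrumTable(
            self.values[:, idx],
            self.wavelengths[idx],
            list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
            columns=[self.columns[i] for i in idx],
            fused=self.fused,
        )

    def with_values(self, values) -> "SpectrumTable":
        return SpectrumTable(
            values,
            self.wavelengths.copy(),
            list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
            columns=list(self.columns),
            fused=self.fused,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "sample_id", self.sample_ids)
        lab = (
            ["" for _ in self.sample_ids]
            if self.labels is None
            else [LABEL_NAMES[l] for l in self.labels]
        )
        df.insert(1, "label", lab)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fused: bool = False) -> "SpectrumTable":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise ValueError("spectrum CSV must have sample_id and label columns")
        cols = [c for c in df.columns if c not in ("sample_id", "label")]
        wl = np.array([float(c.split(":", 1)[-1]) for c in cols])
        labels = None
        lab = df["label"].fillna("").astype(str)
        if (lab != "").all():
            labels = np.array([LABEL_CODES[v] for v in lab])
        return cls(
            df[cols].to_numpy(float),
            wl,
            list(df["sample_id"].astype(str)),
            labels=labels,
            columns=cols,
            fused=fused,
        )


@dataclass
class Hypercube:
    """rows x cols x bands reflectance cube for one instrument."""

    values: np.ndarray
    wavelengths: np.ndarray
    instrument: str = ""

    def __post_init__(self):
        self.values = _as_float_array(self.values, 3)
        self.wavelengths = _as_float_array(self.wavelengths, 1)
        if self.values.shape[2] != len(self.wavelengths):
            raise ValueError("band axis does not match wavelength list")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    def band_index(self, band_nm: float) -> int:
        """Nearest band to ``band_nm``; ties resolve to the lower band."""
        wl = self.wavelengths
        if band_nm < wl[0] or band_nm > wl[-1]:
            raise ValueError(
                f"requested band {band_nm} nm outside range "
                f"[{wl[0]}, {wl[-1]}] of instrument {self.instrument!r}"
            )
        d = np.abs(wl - band_nm)
        # argmin returns the first (lower-wavelength) index on ties
        return int(np.argmin(d))

    def band_image(self, band_nm: float) -> np.ndarray:
        return self.values[:, :, self.band_index(band_nm)]


@dataclass
class PixelMask:
    """Boolean foreground mask with connected-component labels."""

    mask: np.ndarray
    object_labels: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.object_labels = np.asarray(self.object_labels, dtype=int)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-d")
        if self.object_labels.shape != self.mask.shape:
            raise ValueError("label image shape mismatch")
        if np.any((self.object_labels > 0) != self.mask):
            raise ValueError("labels inconsistent with mask")

    @property
    def n_objects(self) -> int:
        return int(self.object_labels.max())
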