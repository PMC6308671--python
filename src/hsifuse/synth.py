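"""Seeded synthetic data emulating two complementary hyperspectral imagers.

Instrument A ("PB", push-broom style) covers 480-960 nm; instrument B
("LCTF") covers 965-1655 nm in 5 nm steps.  The generative model encodes the
qualitative structure the downstream analysis assumes:

* healthy baseline: smooth logistic rise from a dark visible region into a
  bright NIR/SWIR plateau, minus Gaussian absorption dips near 980, 1200
  and 1460 nm;
* bruising lowers reflectance only above 700 nm, in proportion to a
  per-sample severity;
* each instrument observes the bruise signal through its own independent
  latent factor, mixed in with weight ``complementarity`` — so with
  complementarity > 0 neither instrument alone carries the full class
  signal;
* a "calyx-like" subgroup of bruised samples has the effect attenuated by
  ``calyx_gamma``, producing hard false negatives;
* ground truth is a bruise area ratio; samples are labeled bruised when it
  reaches ``ratio_threshold`` (default 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datatypes import BRUISED, HEALTHY, Hypercube, PixelMask, SpectrumTable


def default_grid_pb(n_bands: int = 102) -> np.ndarray:
    """Evenly spaced band centers spanning 480-960 nm."""
    return np.linspace(480.0, 960.0, n_bands)


def default_grid_lctf() -> np.ndarray:
    """965, 970, ..., 1655 nm (139 bands, 5 nm steps)."""
    return np.arange(965.0, 1655.0 + 2.5, 5.0)


@dataclass
class SyntheticConfig:
    n_healthy: int = 120
    n_bruised: int = 120
    seed: int = 0
    band_grid_pb: np.ndarray = field(default_factory=default_grid_pb)
    band_grid_lctf: np.ndarray = field(default_factory=default_grid_lctf)
    dip_centers: tuple = (980.0, 1200.0, 1460.0)
    dip_widths: tuple = (35.0, 45.0, 55.0)
    dip_depths: tuple = (0.10, 0.14, 0.22)
    effect_size: float = 0.065
    noise_sd_pb: float = 0.005
    noise_sd_lctf: float = 0.004
    scatter_sd: float = 0.02
    complementarity: float = 0.5
    latent_sd: float = 0.9
    nuisance_components: int = 20
    nuisance_sd: float = 0.03
    nuisance_df: float = float("inf")  # < inf: Student-t clutter amplitudes
    nuisance_scale: float = 1.0  # session factor; >1 emulates acquisition drift
    session: int = 0  # acquisition session; shifts clutter shapes slightly
    calyx_fraction: float = 0.25
    calyx_gamma: float = 0.4
    # per-instrument overrides: calyx bruises sit near the fruit edge and
    # are largely missed by the line-scan view but caught in the SWIR range
    calyx_gamma_pb: float | None = 0.15
    calyx_gamma_lctf: float | None = 0.8
    # healthy-sample water-content variability visible only in the SWIR
    # instrument; costs it specificity while it stays the more sensitive one
    healthy_drop_sd_lctf: float = 0.012
    # specular-glare artifacts: a fraction of samples acquire a spurious
    # brightening over the NIR signal region of the line-scan imager
    # (sample surface orientation); typically a prediction-session problem
    glare_frac: float = 0.0
    glare_sd: float = 0.08
    ratio_threshold: float = 0.25
    severity: float | None = None  # fix severity (e.g. 1.0) instead of Beta(5,2)

    def __post_init__(self):
        self.band_grid_pb = np.asarray(self.band_grid_pb, float)
        self.band_grid_lctf = np.asarray(self.band_grid_lctf, float)
        if self.n_healthy <= 0 or self.n_bruised <= 0:
            raise ValueError("sample counts must be positive")
        for grid in (self.band_grid_pb, self.band_grid_lctf):
            if len(grid) < 2:
                raise ValueError("band grid must have at least 2 bands")
            if not np.all(np.diff(grid) > 0):
                raise ValueError("band grid must be strictly increasing")
        for sd in (self.noise_sd_pb, self.noise_sd_lctf, self.scatter_sd,
                   self.latent_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for frac, name in ((self.complementarity, "complementarity"),
                           (self.calyx_gamma, "calyx_gamma"),
                           (self.calyx_fraction, "calyx_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SampleTruth:
    sample_id: str
    bruise_ratio: float
    severity: float
    label: int  # +1 healthy / -1 bruised
    subgroup: str  # control | stem | equator | calyx


def healthy_baseline(wl: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Expected healthy reflectance on the grid ``wl``."""
    wl = np.asarray(wl, float)
    base = 0.08 + 0.55 / (1.0 + np.exp(-(wl - 650.0) / 45.0))
    for c, w, d in zip(config.dip_centers, config.dip_widths, config.dip_depths):
        base = base - d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return base


def nuisance_loadings(wl: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Fixed smooth class-independent variance components, (k, bands).

    Gaussian bumps with centers spread across the instrument range; they
    model structured clutter (illumination drift, surface curvature) whose
    per-sample amplitudes are random but whose shapes are part of the
    instrument, hence identical for any table drawn on the same grid.
    Clutter is attenuated near the bruise-signal centers, so a handful of
    wavelengths carry most of the usable class information.
    """
    wl = np.asarray(wl, float)
    k = config.nuisance_components
    if k == 0 or config.nuisance_sd == 0:
        return np.zeros((0, len(wl)))
    span = wl[-1] - wl[0]
    centers = np.linspace(wl[0] + 0.05 * span, wl[-1] - 0.05 * span, k)
    widths = span / 10.0 * (1.0 + 0.5 * np.cos(np.arange(k)))
    if config.session != 0:
        jitter_rng = np.random.default_rng(1_000_003 * config.session)
        centers = centers + jitter_rng.uniform(-1.0, 1.0, k) * span / k
        widths = widths * jitter_rng.uniform(0.6, 1.6, k)
    # clutter is confined to bands away from the absorption-stable signal
    # centers, so the informative bands stay clean
    quiet = (_signal_bumps(wl) < 0.2).astype(float)
    out = np.empty((k, len(wl)))
    for i in range(k):
        out[i] = config.nuisance_sd * quiet * np.exp(
            -0.5 * ((wl - centers[i]) / widths[i]) ** 2)
    return out


SIGNAL_CENTERS = (750.0, 860.0, 940.0, 980.0, 1200.0, 1460.0)
SIGNAL_WIDTH = 15.0


def _signal_bumps(wl: np.ndarray) -> np.ndarray:
    wl = np.asarray(wl, float)
    bumps = np.zeros_like(wl)
    for c in SIGNAL_CENTERS:
        bumps = bumps + np.exp(-0.5 * ((wl - c) / SIGNAL_WIDTH) ** 2)
    return np.minimum(bumps, 1.0)


def bruise_window(wl: np.ndarray) -> np.ndarray:
    """Smooth bruise-effect profile: zero below ~700 nm, positive above.

    Above the 720 nm ramp the effect is a broad floor plus bumps at
    water/pigment-related centers, so the discriminative signal is
    concentrated around a handful of wavelengths rather than spread
    uniformly.  Peak value is ~1 so ``effect_size`` is the peak drop.
    """
    wl = np.asarray(wl, float)
    ramp = 1.0 / (1.0 + np.exp(-(wl - 720.0) / 12.0))
    ramp = ramp * (wl >= 700.0)  # strictly zero in the visible region
    return ramp * (0.005 + 0.995 * _signal_bumps(wl))


def bruised_mean_curve(wl: np.ndarray, config: SyntheticConfig,
                       severity: float = 1.0) -> np.ndarray:
    return healthy_baseline(wl, config) - severity * config.effect_size * bruise_window(wl)


def _draw_truth(config: SyntheticConfig, rng: np.random.Generator):
    """Sample ids, severities, subgroups and labels.

    Treated samples draw severity from Beta(5, 2) (unless fixed by config)
    and a bruise ratio = severity * U(0.6, 1.0); draws falling below the
    labeling threshold are rejected so the bruised group size is exact.
    """
    truths = []
    subgroups = ["stem", "equator", "calyx"]
    n_total = config.n_healthy + config.n_bruised
    ids = [f"S{i:04d}" for i in range(n_total)]
    for i in range(config.n_healthy):
        truths.append(SampleTruth(ids[i], 0.0, 0.0, HEALTHY, "control"))
    n_calyx = int(round(config.calyx_fraction * config.n_bruised))
    for j in range(config.n_bruised):
        sub = "calyx" if j < n_calyx else subgroups[j % 2]
        for _ in range(1000):
            sev = (config.severity if config.severity is not None
                   else float(rng.beta(5.0, 2.0)))
            ratio = sev * float(rng.uniform(0.6, 1.0))
            if ratio >= config.ratio_threshold:
                break
        else:
            raise RuntimeError("could not draw a bruised-severity sample")
        truths.append(SampleTruth(ids[config.n_healthy + j], ratio, sev,
                                  BRUISED, sub))
    order = rng.permutation(n_total)
    return [truths[k] for k in order]


def generate_mean_spectra(config: SyntheticConfig):
    """Paired mean-spectrum tables for the two instruments plus ground truth.

    Returns ``(table_pb, table_lctf, truths)`` with identical sample ids and
    order in both tables.  Reproducible per ``config.seed``; the two
    instruments use independent child streams so their noise is independent.
    """
    master = np.random.SeedSequence(config.seed)
    seq_truth, seq_a, seq_b = master.spawn(3)
    rng_truth = np.random.default_rng(seq_truth)
    rng_a = np.random.default_rng(seq_a)
    rng_b = np.random.default_rng(seq_b)

    truths = _draw_truth(config, rng_truth)
    n = len(truths)
    labels = np.array([t.label for t in truths])
    sev = np.array([t.severity for t in truths])
    is_calyx = np.array([t.subgroup == "calyx" for t in truths])
    healthy = labels == HEALTHY

    rho = config.complementarity
    tables = []
    for wl, rng, noise_sd, name in (
        (config.band_grid_pb, rng_a, config.noise_sd_pb, "PB"),
        (config.band_grid_lctf, rng_b, config.noise_sd_lctf, "LCTF"),
    ):
        g_override = (config.calyx_gamma_pb if name == "PB"
                      else config.calyx_gamma_lctf)
        g = config.calyx_gamma if g_override is None else g_override
        gamma = np.where(is_calyx, g, 1.0)
        eff = sev * gamma  # per-sample effective severity seen by this imager
        base = healthy_baseline(wl, config)
        window = bruise_window(wl)
        # instrument-private latent factor: mean 1, nonnegative, so the
        # expected drop matches the configured curve for any rho
        if config.latent_sd > 0:
            k = 1.0 / config.latent_sd**2
            factor = rng.gamma(shape=k, scale=1.0 / k, size=n)
        else:
            factor = np.ones(n)
        drop_scale = eff * ((1.0 - rho) + rho * factor)
        if name == "LCTF" and config.healthy_drop_sd_lctf > 0:
            # healthy-berry water variation mimics a faint bruise in SWIR
            hdrop = np.abs(rng.standard_normal(n)) * (
                config.healthy_drop_sd_lctf / config.effect_size)
            drop_scale = drop_scale + np.where(healthy, hdrop, 0.0)
        spectra = base[None, :] - np.outer(drop_scale * config.effect_size,
                                           window)
        if config.scatter_sd > 0:
            spectra = spectra * (1.0 + config.scatter_sd
                                 * rng.standard_normal(n))[:, None]
        loadings = nuisance_loadings(wl, config)
        if len(loadings):
            # heavy-tailed amplitudes: occasional glint/shadow artifacts
            if np.isfinite(config.nuisance_df):
                amps = rng.standard_t(config.nuisance_df,
                                      size=(n, len(loadings)))
            else:
                amps = rng.standard_normal((n, len(loadings)))
            spectra = spectra + config.nuisance_scale * (amps @ loadings)
        if name == "PB" and config.glare_frac > 0:
            hit = rng.random(n) < config.glare_frac
            amp = np.abs(rng.standard_normal(n)) * config.glare_sd * hit
            spectra = spectra + np.outer(amp, _signal_bumps(wl))
        if noise_sd > 0:
            # detector noise is lowest near the well-lit signal centers
            band_sd = noise_sd * (1.0 + 1.5 * (1.0 - _signal_bumps(wl)))
            spectra = spectra + band_sd[None, :] * rng.standard_normal(
                spectra.shape)
        tables.append(SpectrumTable(
            spectra, wl, [t.sample_id for t in truths], labels=labels.copy(),
        ))
    return tables[0], tables[1], truths


def sparse_band_table(n_healthy: int, n_bruised: int, wavelengths,
                      informative_idx, effect: float, noise_sd: float,
                      seed: int = 0, nuisance_sd: float = 0.0
                      ) -> SpectrumTable:
    """Flat-spectrum table where only ``informative_idx`` bands carry the
    class difference — used for structure-recovery experiments.

    ``nuisance_sd`` adds a class-independent per-sample factor loading onto
    the *uninformative* bands only, so dragging them into a model adds
    variance without signal.
    """
    rng = np.random.default_rng(seed)
    wl = np.asarray(wavelengths, float)
    n = n_healthy + n_bruised
    p = len(wl)
    labels = np.array([HEALTHY] * n_healthy + [BRUISED] * n_bruised)
    order = rng.permutation(n)
    labels = labels[order]
    X = 0.5 + noise_sd * rng.standard_normal((n, p))
    drop = np.zeros(p)
    informative_idx = np.asarray(informative_idx, int)
    drop[informative_idx] = effect
    X = X - np.outer((labels == BRUISED).astype(float), drop)
    if nuisance_sd > 0:
        loadings = np.zeros(p)
        noise_bands = np.setdiff1d(np.arange(p), informative_idx)
        loadings[noise_bands] = nuisance_sd * (
            0.5 + rng.random(len(noise_bands)))
        X = X + np.outer(rng.standard_normal(n), loadings)
    ids = [f"S{i:04d}" for i in range(n)]
    return SpectrumTable(X, wl, ids, labels=labels)


# ---------------------------------------------------------------------------
# cube fixtures


def generate_cube_triplet(config: SyntheticConfig, shape=(32, 32),
                          n_objects: int = 2, radius: int = 6,
                          reflectance: float = 0.5,
                          sepal_ring: bool = False,
                          instrument: str = "LCTF"):
    """Small raw/white/dark cube triplet with disk "fruit" objects.

    The raw cube is constructed so that ``(raw - dark) / (white - dark)``
    recovers the known true reflectance exactly.  With ``sepal_ring`` the
    first object gets a 1-pixel ring whose 1200/1075 band ratio is elevated.

    Returns ``(raw, white, dark, mask_truth, sepal_truth)``.
    """
    rows, cols = shape
    if rows < 8 or cols < 8:
        raise ValueError("cube shape must be at least 8x8")
    wl = (config.band_grid_lctf if instrument == "LCTF"
          else config.band_grid_pb)
    nb = len(wl)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    true_r = np.full((rows, cols, nb), 0.05)  # dark background
    mask_truth = np.zeros((rows, cols), dtype=bool)
    sepal_truth = np.zeros((rows, cols), dtype=bool)

    yy, xx = np.mgrid[0:rows, 0:cols]
    centers = []
    for k in range(n_objects):
        cy = radius + 1 + (k * (2 * radius + 3)) % max(rows - 2 * radius - 2, 1)
        cx = radius + 1 + ((k * 7) % max(cols - 2 * radius - 2, 1))
        cy = int(np.clip(cy, radius + 1, rows - radius - 2))
        cx = int(np.clip(cx, radius + 1, cols - radius - 2))
        centers.append((cy, cx))
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        disk = dist <= radius
        true_r[disk] = reflectance
        mask_truth |= disk
        if sepal_ring and k == 0:
            ring = (dist <= radius) & (dist > radius - 1.5)
            sepal_truth |= ring

    if sepal_ring and nb > 1:
        i1075 = int(np.argmin(np.abs(wl - 1075.0)))
        i1200 = int(np.argmin(np.abs(wl - 1200.0)))
        r_, c_ = np.nonzero(sepal_truth)
        true_r[r_, c_, i1200] = np.minimum(true_r[r_, c_, i1075] * 2.0, 0.99)

    white = np.full((rows, cols, nb), 0.95) + 0.01 * rng.standard_normal(
        (rows, cols, 1))
    dark = np.full((rows, cols, nb), 0.04)
    raw = dark + true_r * (white - dark)

    cubes = tuple(Hypercube(v, wl, instrument) for v in (raw, white, dark))
    labels, _ = ndimage.label(mask_truth)
    return (*cubes, PixelMask(mask_truth, labels), sepal_truth)
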