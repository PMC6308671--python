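import numpy as np
import pytest

from hsifuse.datatypes import BRUISED, HEALTHY, SpectrumTable
from hsifuse.synth import SyntheticConfig, generate_mean_spectra


@pytest.fixture
def small_table():
    """Tiny labeled table: 8 samples x 5 bands, seeded."""
    rng = np.random.default_rng(42)
    wl = np.array([500.0, 600.0, 700.0, 800.0, 900.0])
    labels = np.array([HEALTHY, BRUISED] * 4)
    X = rng.normal(0.5, 0.05, (8, 5))
    X[labels == BRUISED, 3:] -= 0.2
    return SpectrumTable(X, wl, [f"s{i}" for i in range(8)], labels=labels)


@pytest.fixture(scope="session")
def default_tables():
    """One default synthetic draw shared across tests (train-sized)."""
    cfg = SyntheticConfig(n_healthy=60, n_bruised=60, seed=7)
    return generate_mean_spectra(cfg)


def make_separable_table(n_per_class=60, p=20, delta=1.0, noise=0.2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([HEALTHY] * n_per_class + [BRUISED] * n_per_class)
    labels = labels[rng.permutation(len(labels))]
    X = rng.normal(0.0, noise, (len(labels), p))
    X[:, 0] += delta * (labels == HEALTHY)
    wl = np.linspace(500, 900, p)
    return SpectrumTable(X, wl, [f"s{i}" for i in range(len(labels))],
                        labels=labels)
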