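import numpy as np
import pytest
from hypothesis import settings

from kalium import synthetic_data as sd
from kalium.spectra_io import SpectraSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_set() -> SpectraSet:
    """A tiny deterministic spectra set (40 samples, 30 bands)."""
    rng = np.random.default_rng(7)
    wl = np.arange(400.0, 430.0)
    n = 40
    k = rng.uniform(0.1, 3.0, size=n)
    base = 0.4 + 0.1 * np.sin(wl / 20.0)
    refl = base[None, :] - 0.05 * np.outer(
        k, np.exp(-0.5 * ((wl - 415.0) / 4.0) ** 2)
    )
    refl += 0.002 * rng.normal(size=(n, wl.size))
    refl = np.clip(refl, 0.0, 1.0)
    ids = [f"T{i:02d}" for i in range(n)]
    return SpectraSet(ids, wl, refl, k, order=0.0)


@pytest.fixture(scope="session")
def default_dataset() -> SpectraSet:
    """The study-scale synthetic dataset (301 x 2101), default preset."""
    return sd.generate_dataset(sd.default_config())
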