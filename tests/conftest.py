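import numpy as np
import pytest

from memprobe.model import KBT_ROOM, MembraneParams, WavenumberBand


@pytest.fixture(scope="session")
def nochol_params() -> MembraneParams:
    """Tense no-cholesterol vesicle parameter set (SI)."""
    return MembraneParams(
        kappa_c=7.3 * KBT_ROOM, sigma=1.1e-6, epsilon=0.1, d=2e-9,
        b=6.9e8, eta=1e-3, eta_m=1.2e-9,
    )


@pytest.fixture(scope="session")
def chol_params() -> MembraneParams:
    """Cholesterol-rich vesicle parameter set."""
    return MembraneParams(
        kappa_c=19.2 * KBT_ROOM, sigma=4.5e-6, epsilon=0.1, d=2e-9,
        b=1.2e9, eta=1e-3, eta_m=17.7e-9,
    )


@pytest.fixture(scope="session")
def band() -> WavenumberBand:
    """R = 7 um vesicle probed by a l = 140 nm rod."""
    return WavenumberBand.from_geometry(R=7e-6, l=140e-9)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
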