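import numpy as np
import pytest
from hypothesis import settings

from telenb import CaptureModel, GenomeConfig, TelegraphParams, simulate_genome

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def tele_bursty() -> TelegraphParams:
    """Bursty-regime parameters (sigma_on << sigma_off)."""
    return TelegraphParams(rho=15.0, sigma_on=0.09, sigma_off=0.21)


@pytest.fixture(scope="session")
def tele_intermediate() -> TelegraphParams:
    return TelegraphParams.from_fon_nsigma(15.0, 0.3, 10.0)


@pytest.fixture(scope="session")
def beta_capture() -> CaptureModel:
    return CaptureModel.beta(15.0, 35.0)


@pytest.fixture(scope="session")
def reference_genome():
    """The full reference synthetic genome: 2800 genes x 1000 cells,
    f_on in {0.1..0.7}, N_sigma=10, rho=15, Beta(15,35) capture."""
    return simulate_genome(GenomeConfig(seed=20260922))


def random_telegraph_params(rng: np.random.Generator) -> TelegraphParams:
    """Random parameter set over the physically scanned ranges."""
    rho = rng.uniform(1.0, 20.0)
    fon = rng.uniform(0.05, 0.95)
    nsig = 10.0 ** rng.uniform(-1.0, 3.0)
    return TelegraphParams.from_fon_nsigma(rho, fon, nsig)
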