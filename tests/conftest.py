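import numpy as np
import pytest

from spinbath.acquisition import MTAcquisition
from spinbath.tissue import TissueParameters


@pytest.fixture(scope="session")
def acq() -> MTAcquisition:
    """Default seven-offset Gaussian-pulse acquisition."""
    return MTAcquisition()


@pytest.fixture(scope="session")
def gm_params() -> TissueParameters:
    """Representative gray-matter two-pool parameters."""
    return TissueParameters(f=0.12, kr=20.0, t2r=10e-6, t2f=60e-3, t1f=1.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_valid_params(rng: np.random.Generator, n: int) -> list[TissueParameters]:
    """Physically plausible random two-pool parameter sets."""
    out = []
    for _ in range(n):
        out.append(
            TissueParameters(
                f=float(rng.uniform(0.02, 0.25)),
                kr=float(rng.uniform(5.0, 60.0)),
                t2r=float(rng.uniform(6e-6, 18e-6)),
                t2f=float(rng.uniform(40e-3, 100e-3)),
                t1f=float(rng.uniform(0.8, 1.8)),
                sdf=float(rng.uniform(0.5, 1.5)),
            )
        )
    return out
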