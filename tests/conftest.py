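import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lnvlight.synth_ephys import EphysGenotypeParams, SweepProtocol

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def control_params() -> EphysGenotypeParams:
    """Control-genotype generator parameters (4.2 Hz baseline, blue fold-change)."""
    return EphysGenotypeParams(
        baseline_rate=4.2,
        fold_change={365: 1.667, 450: 1.958, 635: 1.197},
        decay_tau={365: 6.0, 450: 25.0, 635: 0.0},
    )


@pytest.fixture
def blue_protocol() -> SweepProtocol:
    return SweepProtocol(wavelength=450)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
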