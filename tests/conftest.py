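import numpy as np
import pytest

from myofiber import Protocol, SchemeParams
from myofiber.synth import cohort_config


@pytest.fixture
def perfused_params() -> SchemeParams:
    """Crossbridge-scheme rates of the perfused control group."""
    return SchemeParams(k1=26.6, k_minus1=42.3, K2=39.4)


@pytest.fixture
def ischemic_params() -> SchemeParams:
    return SchemeParams(k1=18.9, k_minus1=30.7, K2=24.5)


@pytest.fixture
def perfused_cfg():
    return cohort_config("perfused", seed=42)


@pytest.fixture
def ca_jump() -> Protocol:
    return Protocol(kind="CA_JUMP", pCa=4.5, pi_mM=0.0, duration=0.5, rate_hz=1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
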