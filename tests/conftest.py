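import numpy as np
import pytest

from alifp.params import ModelParams
from alifp.stimulus import BiphasicPulse


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Default (fitted) model parameterization, shared across tests."""
    return ModelParams()


def monophasic(amp: float, phase: float = 100e-6, t_start: float = 0.0) -> BiphasicPulse:
    """Cathodic monophasic pulse of amplitude magnitude ``amp``."""
    return BiphasicPulse(t_start=t_start, a_lead=-amp, d_lead=phase)


def biphasic(
    amp: float, phase: float = 100e-6, ipg: float = 0.0, t_start: float = 0.0
) -> BiphasicPulse:
    """Cathodic-leading, charge-balanced biphasic pulse."""
    return BiphasicPulse(
        t_start=t_start, a_lead=-amp, d_lead=phase, d_ipg=ipg, a_second=amp, d_second=phase
    )


def closed_form_i50(params: ModelParams, d: float) -> float:
    """Strength-duration relation for a monophasic pulse at rest."""
    return params.threshold.m_theta / (
        abs(params.membrane.resistance) * (1.0 - np.exp(-d / params.membrane.tau))
    )
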