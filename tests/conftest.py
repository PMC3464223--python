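import numpy as np
import pytest

import qrpop
from qrpop import ExpKernelSum, NeuronModel, Trace


@pytest.fixture(scope="session")
def model() -> NeuronModel:
    """Calibrated default model (L2/3-pyramidal-like two-exponential SAP)."""
    return qrpop.default_model()


@pytest.fixture(scope="session")
def poisson_model(model) -> NeuronModel:
    """Same scales but no spike after-potential: an inhomogeneous Poisson neuron."""
    return NeuronModel(lambda0=model.lambda0, kappa=model.kappa, eta=ExpKernelSum(()))


@pytest.fixture(scope="session")
def blocked_model(model) -> NeuronModel:
    """Absolute refractory block only (classic renewal closed form)."""
    return NeuronModel(
        lambda0=0.01, kappa=model.kappa, eta=ExpKernelSum((), absolute_block=50.0)
    )


def constant_h(value: float, duration: float, dt: float = 0.5) -> Trace:
    return Trace(dt, np.full(int(round(duration / dt)), float(value)), unit="")


@pytest.fixture(scope="session")
def step_h(model):
    """Filtered input of a 10->70 pA step at t=500 ms, 4.5 s at dt=0.5 ms."""
    current = qrpop.step_current(10.0, 60.0, 500.0, 4500.0, 0.5)
    return qrpop.filtered_input(current, model.kappa)
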