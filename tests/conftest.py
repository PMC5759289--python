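import numpy as np
import pytest

from thyrotx import (
    ModelParameters,
    PatientState,
    builtin_patient,
    hypothetical_patient,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Average-patient parameter constants."""
    return ModelParameters()


@pytest.fixture(scope="session")
def e0(params) -> PatientState:
    """Untreated hyperthyroid start of the hypothetical patient."""
    return hypothetical_patient()[1]


@pytest.fixture(scope="session")
def patient20():
    return builtin_patient(20)


@pytest.fixture(scope="session")
def patient31():
    return builtin_patient(31)


def random_positive_params(rng: np.random.Generator, spread: float = 10.0) -> ModelParameters:
    """Log-uniform draw around the default constants (factor `spread` each way)."""
    base = ModelParameters().to_dict()
    draw = {
        name: float(value * spread ** rng.uniform(-1.0, 1.0)) for name, value in base.items()
    }
    return ModelParameters.from_dict(draw)
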