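import numpy as np
import pytest

from oralpk import (
    DoseEvent,
    RateConstants,
    TransferCoefficients,
    recover_rate_constants,
)
from oralpk import data as study_data


@pytest.fixture(scope="session")
def coeffs_without() -> TransferCoefficients:
    """Transfer coefficients identified for the tenside-free condition."""
    return study_data.COEFFS_WITHOUT


@pytest.fixture(scope="session")
def coeffs_with() -> TransferCoefficients:
    """Transfer coefficients identified for the with-tenside condition."""
    return study_data.COEFFS_WITH


@pytest.fixture(scope="session")
def branches_with(coeffs_with):
    """Exact rate-constant branches recovered from the with-tenside coefficients."""
    return recover_rate_constants(coeffs_with).branches


@pytest.fixture(scope="session")
def branches_without(coeffs_without):
    return recover_rate_constants(coeffs_without).branches


@pytest.fixture
def impulse_dose() -> DoseEvent:
    return DoseEvent(amount=50.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20211509)


def random_rate_constants(rng: np.random.Generator, n: int) -> list[RateConstants]:
    """Random valid triplets with strictly positive ka (so outflow exists)."""
    draws = rng.uniform(0.01, 5.0, size=(n, 3))
    return [RateConstants(ka=a, ke1=b, ke2=c) for a, b, c in draws]
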