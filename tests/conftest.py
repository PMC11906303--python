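import numpy as np
import pytest

from nosbal.reconciliation import RateVector
from nosbal.stoichiometry import default_species


@pytest.fixture(scope="session")
def species():
    """The canonical eight-species acetate/N2O system."""
    return default_species()


@pytest.fixture
def catabolic_rates():
    """Exactly catabolic measured rates (no growth), mmol/d."""
    return RateVector(
        rates={"acetate": -10.0, "N2O": -40.0, "NH4": 0.0, "biomass": 0.0},
        sd={"acetate": 0.5, "N2O": 2.0, "NH4": 0.1, "biomass": 0.1},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
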