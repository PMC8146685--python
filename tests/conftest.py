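import pytest

from gepnet_cea.lifetable import LifeTable, load_bundled_life_table
from gepnet_cea.parameters import ParameterSet

import numpy as np


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    """The bundled synthetic US-like life table."""
    return load_bundled_life_table()


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    """Base-case parameters of the decision model."""
    return ParameterSet()


@pytest.fixture
def no_background_lt() -> LifeTable:
    """Life table with zero mortality before the terminal age.

    Isolates disease-specific dynamics: background death never fires for
    a cohort starting at 60 with a 40-year horizon.
    """
    ages = np.arange(0, 101)
    q = np.zeros(101)
    q[-1] = 1.0
    return LifeTable(ages=ages, q_annual=q)
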