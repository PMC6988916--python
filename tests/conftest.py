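import numpy as np
import pandas as pd
import pytest

from forestspat import SampleId, SyntheticScenario, generate_sample
from forestspat.geodata import UnitRecord


@pytest.fixture(scope="session")
def small_sample():
    """A 150-unit synthetic sample with moderate error dependence."""
    scenario = SyntheticScenario(seed=2024, n_units=150)
    units, truth = generate_sample(scenario)
    return units, truth


@pytest.fixture(scope="session")
def sample_id():
    return SampleId("ZAM", "micro")


@pytest.fixture
def rng():
    return np.random.default_rng(77)


def make_unit(unit_id="u0", country="ZAM", level="micro", A_TOT=200.0,
              FA=50.0, FA_pot=100.0, P_TOT=1000.0, R_TOT=4.0,
              FL_TOT=120.0, CSI=40.0, CY=None, centroid=(0.0, 0.0)):
    return UnitRecord(unit_id=unit_id, country=country, level=level,
                      A_TOT=A_TOT, FA=FA, FA_pot=FA_pot, P_TOT=P_TOT,
                      R_TOT=R_TOT, FL_TOT=FL_TOT, CSI=CSI, CY=CY,
                      centroid=centroid)


@pytest.fixture
def unit_factory():
    return make_unit


def random_design(rng, n, p, names=None):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=names or [f"x{i}" for i in range(p)])
    return X
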