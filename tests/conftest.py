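import numpy as np
import pytest

from emgforce import MuscleTendonParams, PhysioParams, UniformSeries


@pytest.fixture(scope="session")
def gas() -> MuscleTendonParams:
    return MuscleTendonParams.gastrocnemius()

@pytest.fixture(scope="session")
def sol() -> MuscleTendonParams:
    return MuscleTendonParams.soleus()


@pytest.fixture(scope="session")
def physio_gas(gas) -> PhysioParams:
    return PhysioParams.from_muscle(gas)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def series(values, dt=1e-3, t0=0.0) -> UniformSeries:
    return UniformSeries(dt=dt, values=np.asarray(values, dtype=float), t0=t0)


@pytest.fixture(scope="session")
def make_series():
    return series
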