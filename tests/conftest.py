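import pytest

from cropresid import datasets
from cropresid.datamodel import ResidueSample, ResidueSeries


@pytest.fixture(scope="session")
def spinach():
    return datasets.spinach_crop_parameters()


@pytest.fixture(scope="session")
def pesticides():
    return datasets.pesticide_properties()


@pytest.fixture(scope="session")
def pencycuron(pesticides):
    return next(p for p in pesticides if p.name == "pencycuron")


@pytest.fixture(scope="session")
def schedules(pesticides):
    return datasets.default_schedules(pesticides)


def make_series(times, concentrations, pesticide="test", replicate="r1"):
    return ResidueSeries(
        pesticide=pesticide,
        samples=tuple(ResidueSample(time=t, concentration=c,
                                    replicate_id=replicate)
                      for t, c in zip(times, concentrations)))


@pytest.fixture
def exact_decay_series():
    """Noiseless C(t) = 10·exp(−0.2 t) on t = 0,1,3,7,14."""
    import numpy as np
    t = [0.0, 1.0, 3.0, 7.0, 14.0]
    return make_series(t, list(10.0 * np.exp(-0.2 * np.asarray(t))))
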