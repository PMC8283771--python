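import pytest

from splicepairs.pairing import u5_loop1, u6_acagaga
from splicepairs.simulate import SiteFrequencyModel, generate_dataset
from splicepairs.dataset import classify_dataset


@pytest.fixture(scope="session")
def u5():
    return u5_loop1()


@pytest.fixture(scope="session")
def u6():
    return u6_acagaga()


@pytest.fixture(scope="session")
def small_dataset():
    """200 synthetic introns, no injected dependency, classified."""
    ds = generate_dataset(SiteFrequencyModel(), 200, seed=11)
    classify_dataset(ds)
    return ds


@pytest.fixture(scope="session")
def medium_dataset():
    """2,000 synthetic introns with the -1G/+5G dependency injected."""
    ds = generate_dataset(SiteFrequencyModel(delta_5ss=0.15), 2000, seed=23)
    classify_dataset(ds)
    return ds
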