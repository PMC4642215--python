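import numpy as np
import pytest

from qconj import MembershipTriplet


def triplet(mu_a, mu_b, mu_ab, name="p", a="A", b="B"):
    return MembershipTriplet(exemplar=name, concept_a=a, concept_b=b,
                             mu_a=mu_a, mu_b=mu_b, mu_ab=mu_ab)


@pytest.fixture
def rng():
    return np.random.default_rng(20151112)


@pytest.fixture
def sailboat():
    return triplet(0.56, 0.8, 0.42, "sailboat", "Machine", "Vehicle")


@pytest.fixture
def skateboard():
    return triplet(0.28, 0.84, 0.34, "skateboard", "Machine", "Vehicle")


@pytest.fixture
def cave():
    return triplet(0.28, 0.85, 0.28, "cave", "Building", "Dwelling")


@pytest.fixture
def synagogue():
    return triplet(0.93, 0.49, 0.45, "synagogue", "Building", "Dwelling")


@pytest.fixture
def filing_cabinet():
    return triplet(0.97, 0.31, 0.53, "filing cabinet", "Furniture", "Household Appliances")


@pytest.fixture
def heated_waterbed():
    return triplet(1.0, 0.49, 0.78, "heated waterbed", "Furniture", "Household Appliances")
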