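import numpy as np
import pytest

from epigrn.er_model import ERParams
from epigrn.params import reference_er_params, reference_grn_params


@pytest.fixture(scope="session")
def ders1():
    return reference_er_params("ders1")


@pytest.fixture(scope="session")
def ders2():
    return reference_er_params("ders2")


@pytest.fixture(scope="session")
def pers1():
    return reference_er_params("pers1")


@pytest.fixture(scope="session")
def pers2():
    return reference_er_params("pers2")


@pytest.fixture(scope="session")
def reference_er():
    return reference_er_params("reference")


@pytest.fixture(scope="session")
def grn():
    return reference_grn_params()


@pytest.fixture
def unit_er_params():
    """All sixteen rate constants equal to one (hand-evaluable propensities)."""
    return ERParams(c=np.ones(16), n_sites=15, e_hdm=5, e_hdac=5)
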