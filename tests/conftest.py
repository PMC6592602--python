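import numpy as np
import pytest

from nemamix.doseresponse import load_reference_lc_table
from nemamix.experiments import reference_curves
from nemamix.simulate import HazardModel


@pytest.fixture(scope="session")
def lc_tables():
    return load_reference_lc_table()


@pytest.fixture(scope="session")
def curves():
    return reference_curves()


@pytest.fixture(scope="session")
def ia_model(curves):
    return HazardModel(curves=curves, mode="IA")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
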