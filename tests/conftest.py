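import numpy as np
import pytest

from nfkblink.datamodel import ExpressionMatrix, RegulatoryNetwork, TimeGrid
from nfkblink.kinetics import default_model, equilibrate


@pytest.fixture(scope="session")
def model():
    """The bundled 24-species NF-κB module."""
    return default_model()


@pytest.fixture(scope="session")
def resting_state(model):
    """Steady state at basal IKK = 1e-4, shared across kinetics tests."""
    return equilibrate(model, 1e-4)


@pytest.fixture
def small_expr():
    """3 genes x 2 times, one condition."""
    return ExpressionMatrix(
        ["g1", "g2", "g3"], ["c1"], {"c1": TimeGrid([0.0, 2.0])},
        np.array([[0.0, 1.0], [0.5, -0.5], [2.0, 0.25]]),
    )


@pytest.fixture
def small_net():
    """2 TFs, 3 genes, 4 edges."""
    return RegulatoryNetwork(
        ["T1", "T2"], ["g1", "g2", "g3"],
        [("T1", "g1", 1), ("T1", "g2", -1), ("T2", "g2", 0), ("T2", "g3", 1)],
    )
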