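import numpy as np
import pytest

from ramapop.geometry import build_conformation, ninemer_spec, xao_spec

# Aqueous-solution XAO basin populations used as generator weights.
TABLE1_WEIGHTS = {
    "PII": 0.534,
    "beta": 0.202,
    "alphaR": 0.126,
    "three10": 0.062,
    "alphaL": 0.041,
    "C7eq": 0.035,
}

PII_ANGLES = (-75.0, 145.0, 180.0)


@pytest.fixture(scope="session")
def xao():
    return xao_spec()


@pytest.fixture(scope="session")
def ninemer():
    return ninemer_spec()


@pytest.fixture(scope="session")
def pii_xao(xao):
    """XAO built with every backbone pair at canonical PII torsions."""
    return build_conformation(xao, PII_ANGLES)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
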