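import numpy as np
import pytest

from glycoflow.network import (reference_loadings, reference_model,
                               reference_parameters, subsystem_loadings)
from glycoflow.reactor import InflowProtocol


@pytest.fixture(scope="session")
def model():
    return reference_model()


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def full_loadings():
    return reference_loadings()


@pytest.fixture(scope="session")
def sub_loadings():
    return subsystem_loadings()


@pytest.fixture()
def washout_protocol():
    """Single-step feed, no equilibration: pure dilution dynamics."""
    return InflowProtocol(segments=((0.0, {"feed": 25.0}),),
                          stocks={"feed": {"G": 1.0}},
                          duration_s=2000.0, equilibration_s=0.0)


@pytest.fixture()
def subsystem_step_protocol():
    """Four 15-min steps of glucose/ATP feeds at constant total flow."""
    segments = tuple(
        (k * 900.0, {"G": 2.0 + k, "ATP": 4.0, "NAD": 2.0,
                     "buf": 17.0 - k})
        for k in range(4))
    return InflowProtocol(
        segments=segments,
        stocks={"G": {"G": 40.0}, "ATP": {"ATP": 40.0},
                "NAD": {"NAD": 20.0}, "buf": {}},
        duration_s=3600.0)


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
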