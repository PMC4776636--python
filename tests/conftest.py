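import numpy as np
import pytest

from dvhpoints import DVHCase, StructureDVH


@pytest.fixture
def linear_dvh() -> StructureDVH:
    """The closed-form workhorse: V(d) = 100 − d cc on [0, 100] Gy."""
    d = np.linspace(0.0, 100.0, 101)
    return StructureDVH("linear", d, 100.0 - d)


@pytest.fixture
def flat_dvh() -> StructureDVH:
    """A flat segment then a drop: doses [0, 10, 20], volumes [50, 50, 0]."""
    return StructureDVH("flat", np.array([0.0, 10.0, 20.0]),
                        np.array([50.0, 50.0, 0.0]))


@pytest.fixture
def truncated_dvh() -> StructureDVH:
    """A curve whose export stops before reaching zero volume."""
    return StructureDVH("trunc", np.array([0.0, 30.0, 60.0]),
                        np.array([80.0, 40.0, 10.0]))


@pytest.fixture
def simple_case(linear_dvh) -> DVHCase:
    return DVHCase("CASE-1", (linear_dvh,), rx_dose=50.0, global_max_dose=100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160303)
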