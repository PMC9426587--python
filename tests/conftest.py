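import pytest

from trichodiel.params import FixedParameters, RunConfig, default_optimized_parameters
from trichodiel.simulator import integrate_diel


@pytest.fixture(scope="session")
def fixed():
    return FixedParameters()


@pytest.fixture(scope="session")
def free_unified():
    return default_optimized_parameters("unified")


@pytest.fixture(scope="session")
def unified_run(fixed, free_unified):
    """Standard optimized unified-trichome diel cycle (shared across tests)."""
    return integrate_diel(fixed, free_unified, RunConfig())


@pytest.fixture(scope="session")
def segregated_run(fixed):
    """Standard optimized spatially-segregated diel cycle, lossless transfer."""
    return integrate_diel(fixed, default_optimized_parameters("segregated"),
                          RunConfig(variant="segregated"))
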