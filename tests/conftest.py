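import pytest

from pm_hia import (
    GemmParameterSet,
    SimulationConfig,
    load_gemm_parameters,
    simulate_panels,
)
from pm_hia.ages import AGE_BANDS


@pytest.fixture(scope="session")
def ihd_params() -> GemmParameterSet:
    return load_gemm_parameters()


@pytest.fixture()
def toy_params() -> GemmParameterSet:
    """Small hand-checkable parameter set shared across modules."""
    return GemmParameterSet(
        cause="TOY",
        entries={b: (0.2, 0.05) for b in AGE_BANDS},
        alpha=2.0,
        mu=10.0,
        nu=5.0,
        counterfactual_conc=2.4,
    )


@pytest.fixture(scope="session")
def default_panels(ihd_params):
    """One seeded draw of the default Seoul-like synthetic panels."""
    return simulate_panels(SimulationConfig(seed=20160101), ihd_params)
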