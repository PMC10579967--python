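import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chromopulse import StimulusProtocol, preset
from chromopulse.params import AdaptationParams, GeneKinetics


@pytest.fixture(scope="session")
def hourly_grid():
    return np.arange(-2.0, 32.0)


@pytest.fixture(scope="session")
def constant10():
    return StimulusProtocol.constant(10.0)


@pytest.fixture(scope="session", params=["IRF1", "CXCL10", "CXCL9"])
def gene_preset(request):
    kin, adapt = preset(request.param)
    return request.param, kin, adapt


@pytest.fixture(scope="session")
def plain_kinetics():
    """A small hand-set parameter vector used where preset calibration is
    irrelevant."""
    return GeneKinetics(
        k1=0.8, k2=0.4, k3=1.2, k4=0.6, k5=5.0, k6=2.0,
        deltaM=1.0, deltaP=0.2, alpha=0.5, Kd=0.1,
    )


@pytest.fixture(scope="session")
def plain_adaptation():
    return AdaptationParams(
        a_regM=10.0, a_regP=1.0, delta_regM=0.5, delta_regP=0.25,
        reg_thr=20.0, c1=2.0, c2=0.5, enabled=True,
    )


@pytest.fixture(scope="session")
def cxcl10_ensemble_1000():
    """Shared constant-10 ng/ml ensemble for the CXCL10-like preset."""
    from chromopulse.stochastic import StochasticConfig, ensemble

    kin, adapt = preset("CXCL10")
    return ensemble(
        kin, adapt, StimulusProtocol.constant(10.0), StochasticConfig(n_cells=1000, seed=101)
    )


@pytest.fixture(scope="session")
def irf1_ensemble_1000():
    from chromopulse.stochastic import StochasticConfig, ensemble

    kin, adapt = preset("IRF1")
    return ensemble(
        kin, adapt, StimulusProtocol.constant(10.0), StochasticConfig(n_cells=1000, seed=101)
    )
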