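import numpy as np
import pytest

from survtarget import DGPParams, generate


@pytest.fixture(scope="session")
def dgp() -> DGPParams:
    return DGPParams()


@pytest.fixture(scope="session")
def big_cohort(dgp):
    """Large draw for parameter-recovery and marginal-frequency checks."""
    return generate(dgp, n=200_000, seed=20260, include_counterfactuals=True)


@pytest.fixture(scope="session")
def cohort5000(dgp):
    """Single replicate at the tutorial's sample size."""
    return generate(dgp, n=5000, seed=11, include_counterfactuals=False)


@pytest.fixture(scope="session")
def cohort2000(dgp):
    return generate(dgp, n=2000, seed=12, include_counterfactuals=False)


@pytest.fixture(scope="session")
def no_censoring_cohort():
    """Binary L, effectively impossible censoring; used for oracle checks."""
    params = DGPParams(delta=(-50.0, 0.0, 0.0))
    return generate(params, n=4000, seed=5, include_counterfactuals=False)


@pytest.fixture(scope="session")
def curves5000(cohort5000):
    """Targeted survival estimates for every (a, t) on the n=5000 replicate."""
    from survtarget import estimate_curves

    return estimate_curves(cohort5000.data)


@pytest.fixture(scope="session")
def curves2000(cohort2000):
    from survtarget import estimate_curves

    return estimate_curves(cohort2000.data)


def mc_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n))
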