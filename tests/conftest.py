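import numpy as np
import pytest

from sogmm import Condition, GrowthParams, LatentClass, MeasurementParams, MixturePopulation
from sogmm.design import LAMBDA_REF, NU_REF, PHI_REF, PSI_REF, THETA_REF, build_population


@pytest.fixture(scope="session")
def reference_growth() -> GrowthParams:
    return GrowthParams(np.array([0.0, 1.0]), PHI_REF.copy(), PSI_REF.copy())


@pytest.fixture(scope="session")
def reference_class(reference_growth) -> LatentClass:
    return LatentClass(
        pi=1.0,
        growth=reference_growth,
        meas=MeasurementParams(LAMBDA_REF.copy(), NU_REF.copy(), THETA_REF.copy()),
    )


@pytest.fixture(scope="session")
def mean_diff_population() -> MixturePopulation:
    return build_population(Condition("loading", "large", "large", 1000, "balanced"))


def random_latent_class(rng) -> LatentClass:
    """Random valid class for property sweeps."""
    a = rng.normal(size=(2, 2))
    phi = a @ a.T + 0.05 * np.eye(2)
    growth = GrowthParams(rng.normal(0, 1, 2), phi, rng.uniform(0.05, 0.6, 4))
    meas = MeasurementParams(
        rng.uniform(0.5, 1.5, 6), rng.normal(0, 0.3, 6), rng.uniform(0.05, 0.6, 6)
    )
    return LatentClass(pi=1.0, growth=growth, meas=meas)
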