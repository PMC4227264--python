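import numpy as np
import pytest

from let7switch.model_core import DimensionalParams, DimensionlessParams


@pytest.fixture
def fig_geometry() -> DimensionlessParams:
    """The branch geometry used throughout the bifurcation analysis:
    gamma = 0.1, gamma2 = 1, gamma3 = 0.5 (alpha and epsilon inert)."""
    return DimensionlessParams(alpha=0.0, gamma=0.1, gamma1=2.482,
                               gamma2=1.0, gamma3=0.5, epsilon=0.02)


@pytest.fixture
def decoupled_params() -> DimensionlessParams:
    """gamma3 = 0: let-7 dynamics decouple from Lin28."""
    return DimensionlessParams(alpha=0.2, gamma=0.1, gamma1=2.0,
                               gamma2=1.0, gamma3=0.0, epsilon=0.375)


def random_dimensionless(rng: np.random.Generator) -> DimensionlessParams:
    """A physiological random parameter set."""
    return DimensionlessParams(
        alpha=rng.uniform(0.0, 0.4),
        gamma=rng.uniform(0.1, 2.0),
        gamma1=rng.uniform(2.0, 5.0),
        gamma2=1.0,
        gamma3=rng.uniform(0.0, 2.5),
        epsilon=rng.uniform(0.02, 1.0),
    )


def random_dimensional(rng: np.random.Generator) -> DimensionalParams:
    return DimensionalParams(
        alpha_M=rng.uniform(0.01, 1.0),
        alpha_P=rng.uniform(0.1, 2.0),
        beta_M=rng.uniform(0.05, 1.0),
        beta_P=rng.uniform(0.1, 2.0),
        kappa_P=rng.uniform(0.05, 2.0),
        Gamma1=rng.uniform(0.5, 5.0),
        Gamma2=rng.uniform(0.2, 3.0),
        Gamma3=rng.uniform(0.1, 3.0),
    )
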