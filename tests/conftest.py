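import numpy as np
import pytest
from hypothesis import settings

import deltapid as dp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


def rdnerr_tensor() -> np.ndarray:
    """X always equals Z; Y equals Z except for a 1/4-probability error."""
    t = np.zeros((2, 2, 2))
    t[0, 0, 0] = 3 / 8
    t[0, 1, 0] = 1 / 8
    t[1, 0, 1] = 1 / 8
    t[1, 1, 1] = 3 / 8
    return t


@pytest.fixture(scope="session")
def rdnerr() -> dp.JointDistribution:
    return dp.JointDistribution(rdnerr_tensor())


@pytest.fixture(scope="session")
def and_dist() -> dp.JointDistribution:
    return dp.function_to_distribution(dp.DiscreteFunction.binary_and())


@pytest.fixture(scope="session")
def xor3_dist() -> dp.JointDistribution:
    return dp.function_to_distribution(dp.DiscreteFunction.xor(3))


@pytest.fixture(scope="session")
def zx3_dist() -> dp.JointDistribution:
    return dp.function_to_distribution(dp.DiscreteFunction.projection_x(3))


@pytest.fixture(scope="session")
def atlas3() -> dp.FunctionAtlas:
    """The full ternary-function atlas (built once per session)."""
    return dp.build_atlas(3)


@pytest.fixture(scope="session")
def atlas2() -> dp.FunctionAtlas:
    return dp.build_atlas(2)


#: reduced optimizer settings for family sweeps (full defaults are used in
#: targeted tests; the sweep only needs ~1e-4 accuracy at the family scale)
SWEEP_BROJA_OPTS = {"n_starts": 3, "n_polish": 12, "consistency_tol": 2e-3}


@pytest.fixture(scope="session")
def library3() -> dp.FunctionLibrary:
    """Full N=3 function-family library with both solvers (built once)."""
    return dp.build_library(
        3, samples_per_family=120, seed=2026, broja_opts=SWEEP_BROJA_OPTS
    )


@pytest.fixture(scope="session")
def library2() -> dp.FunctionLibrary:
    return dp.build_library(2, samples_per_family=80, seed=7)


def random_distributions(n, shapes=((2, 2, 2), (3, 3, 3), (2, 3, 4)), seed=0):
    """Seeded batch of Dirichlet random joint distributions."""
    out = []
    for i in range(n):
        shape = shapes[i % len(shapes)]
        out.append(dp.random_distribution(shape, concentration=1.0, seed=seed + i))
    return out
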