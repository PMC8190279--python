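import numpy as np
import pytest

from zfpk import (
    NoiseModel,
    QuenchSpec,
    default_study_design,
    reference_pk_parameters,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def design():
    compounds, regimens, times = default_study_design()
    return {"compounds": compounds, "regimens": regimens, "times": times}


@pytest.fixture(scope="session")
def truth():
    return reference_pk_parameters()


@pytest.fixture(scope="session")
def three_route_regimens(design):
    return [r for r in design["regimens"] if r.route.value in ("immersion", "PC", "IP")]


@pytest.fixture(scope="session")
def noiseless_dataset(design, truth, three_route_regimens):
    return simulate_dataset(
        truth, design["compounds"], three_route_regimens,
        n_replicates=3, noise=NoiseModel(proportional_cv=0.0, additive_floor=0.0),
        quench=None, seed=11,
    )


@pytest.fixture(scope="session")
def noisy_dataset(design, truth, three_route_regimens):
    return simulate_dataset(
        truth, design["compounds"], three_route_regimens,
        n_replicates=10, noise=NoiseModel(proportional_cv=0.10),
        quench=None, seed=29,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
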