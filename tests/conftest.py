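"""Shared fixtures: case-study parameter vectors and small test designs."""

import numpy as np
import pytest

from bdscreen.dose_response import HillParams, SubpopulationParams
from bdscreen.moments import ModelParams
from bdscreen.simulate import ExperimentDesign


@pytest.fixture(scope="session")
def fig2_params() -> ModelParams:
    """Two slow clones, no drug, no observation noise (CLT-check study)."""
    return ModelParams(
        fractions=(0.4629, 0.5371),
        subpops=(
            SubpopulationParams(0.9058, 0.8101),
            SubpopulationParams(0.2785, 0.2300),
        ),
        noise_c=0.0,
    )


@pytest.fixture(scope="session")
def balanced_mixture() -> ModelParams:
    """Balanced sensitive/resistant two-clone mixture (baseline case study)."""
    return ModelParams(
        fractions=(0.4856, 0.5144),
        subpops=(
            SubpopulationParams(0.1163, 0.0176, HillParams(0.8262, 0.0674, 4.5404)),
            SubpopulationParams(0.4624, 0.3978, HillParams(0.8062, 1.5776, 4.2002)),
        ),
        noise_c=1.2103,
    )


@pytest.fixture(scope="session")
def three_clone_mixture() -> ModelParams:
    """Sensitive / moderate / resistant three-clone mixture."""
    return ModelParams(
        fractions=(0.2135, 0.2718, 0.5147),
        subpops=(
            SubpopulationParams(0.3214, 0.2773, HillParams(0.8782, 0.0344, 2.5998)),
            SubpopulationParams(0.7334, 0.6776, HillParams(0.8506, 0.3558, 4.6055)),
            SubpopulationParams(0.0683, 0.0253, HillParams(0.8614, 1.5764, 4.4706)),
        ),
        noise_c=9.5209,
    )


@pytest.fixture(scope="session")
def high_noise_mixture() -> ModelParams:
    """Two-clone mixture observed with very large counting noise (c = 500)."""
    return ModelParams(
        fractions=(0.3690, 0.6310),
        subpops=(
            SubpopulationParams(0.4380, 0.3422, HillParams(0.8398, 0.0813, 3.9647)),
            SubpopulationParams(0.5320, 0.4767, HillParams(0.8674, 1.9793, 4.8357)),
        ),
        noise_c=500.0,
    )


@pytest.fixture(scope="session")
def unbalanced_mixture() -> ModelParams:
    """99% sensitive cells, 1% resistant clone (minority-detection study)."""
    return ModelParams(
        fractions=(0.9900, 0.0100),
        subpops=(
            SubpopulationParams(0.4301, 0.4199, HillParams(0.8644, 0.0768, 4.3186)),
            SubpopulationParams(0.1458, 0.1258, HillParams(0.8565, 0.5348, 3.7518)),
        ),
        noise_c=4.8400,
    )


@pytest.fixture
def small_design():
    """Tiny screen for fast unit tests."""

    def make(assay="live_cell", n_replicates=4, n_initial=200):
        return ExperimentDesign(
            times=(2.0, 4.0, 6.0),
            doses=(0.0, 0.1, 1.0),
            n_replicates=n_replicates,
            n_initial=n_initial,
            assay=assay,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
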