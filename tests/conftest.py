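import numpy as np
import pytest

from tmsfield.cohort import CohortSpec, sample_cohort
from tmsfield.experiment import DualTargetExperiment, RunConfig
from tmsfield.geometry import generate_head


@pytest.fixture(scope="session")
def small_head():
    """Unperturbed concentric spheres at low mesh density."""
    return generate_head(mesh_density=3, perturbation_amplitude=0.0, seed=0)


@pytest.fixture(scope="session")
def perturbed_head():
    """Perturbed head at the working mesh density used for cohort tests."""
    return generate_head(mesh_density=4, perturbation_amplitude=2.0, seed=11)


@pytest.fixture(scope="session")
def dense_head():
    """Unperturbed head at the density used for ROI metrics."""
    return generate_head(mesh_density=5, perturbation_amplitude=0.0, seed=0)


@pytest.fixture(scope="session")
def default_cohort(perturbed_head):
    """Default calibrated cohort, n=30, fixed seed."""
    return sample_cohort(perturbed_head, CohortSpec(n_subjects=30, rng_seed=0))


@pytest.fixture(scope="session")
def fitted_results():
    """Full experiment fit on the default study conditions (n=30, seed 0)."""
    cfg = RunConfig(n_subjects=30, mesh_density=5, perturbation_amplitude=1.5,
                    seed=0)
    return DualTargetExperiment.from_config(cfg).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
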