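import numpy as np
import pytest
from hypothesis import settings

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fviiipk.population_model import (
    Covariates,
    PopulationModel,
    omega_from_cv,
    published_model,
)
from fviiipk.structural_pk import DispositionParams, DoseEvent, micro_to_macro
from fviiipk.synthetic_cohort import sample_covariates, simulate_subject


@pytest.fixture(scope="session")
def published():
    return published_model()


@pytest.fixture(scope="session")
def table_params():
    """Published typical disposition parameters."""
    return DispositionParams(CL=0.195, V1=2.30, Q=0.078, V2=0.449)


@pytest.fixture(scope="session")
def table_macro(table_params):
    return micro_to_macro(table_params)


@pytest.fixture(scope="session")
def median_covariates():
    """A subject sitting exactly at the published covariate medians."""
    return Covariates(BW=70.0, age=25.0, HT=175.0, FFM=50.5)


@pytest.fixture(scope="session")
def simple_1cpt():
    """Small one-compartment population model for fast estimation tests."""
    return PopulationModel(
        fixed=DispositionParams(CL=0.2, V1=2.5),
        omega=omega_from_cv(0.3, 0.3, 0.0),
        sigma_prop=0.15,
    )


def make_dataset(model, n, times, seed, dose=2000.0, duration=0.0):
    """Simulated records on a shared design (cohort demographics, one dose)."""
    rng = np.random.default_rng(seed)
    covs = sample_covariates(n, rng)
    return [
        simulate_subject(
            model, c, [DoseEvent(dose, 0.0, duration)], times, rng, subject_id=f"S{i}"
        )
        for i, c in enumerate(covs)
    ]


@pytest.fixture(scope="session")
def small_1cpt_dataset(simple_1cpt):
    return make_dataset(simple_1cpt, n=30, times=[1.0, 6.0, 24.0], seed=5)
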