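import numpy as np
import pytest

from vancopk.covariates import CovariateSelection, CovariateVector, PopulationModel
from vancopk.pk import PKParams, Regimen


@pytest.fixture(scope="session")
def median_covariates() -> CovariateVector:
    """The cohort-median covariate vector (defaults of CovariateVector)."""
    return CovariateVector()


@pytest.fixture(scope="session")
def q12h_1g() -> Regimen:
    return Regimen(1000, 12.0, 1.0)


@pytest.fixture(scope="session")
def init_params() -> PKParams:
    """Literature initial estimates used to start the population fits."""
    return PKParams(2.83, 52.14)


def intercept_only_model(cl, v, cv_cl, cv_v, residual_cv=0.10, name="truth"):
    """Covariate-free population model with IIV given as CV fractions."""
    return PopulationModel(
        selection=CovariateSelection(),
        theta_cl=np.array([cl]),
        theta_v=np.array([v]),
        omega=np.diag([(cv_cl * cl) ** 2, (cv_v * v) ** 2]),
        residual_model="proportional",
        residual_scale=residual_cv,
        name=name,
    )


@pytest.fixture(scope="session")
def final_truth() -> PopulationModel:
    """Intercept-only truth at the published final-model estimates."""
    return intercept_only_model(3.16, 60.71, 0.4172, 0.3514)


@pytest.fixture(scope="session")
def basic_truth() -> PopulationModel:
    """Intercept-only truth at the published basic-model estimates."""
    return intercept_only_model(2.63, 55.32, 0.5327, 0.4315)
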