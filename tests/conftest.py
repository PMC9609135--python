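import pytest
from hypothesis import HealthCheck, settings

from adiposcan.cohort import generate_cohort
from adiposcan.config import CohortConfig
from adiposcan.evaluate import fit_models
from adiposcan.preprocess import build_part_datasets

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (seed 1)."""
    return generate_cohort(CohortConfig().with_seed(1))


@pytest.fixture(scope="session")
def part_datasets(default_cohort):
    return build_part_datasets(default_cohort)


@pytest.fixture(scope="session")
def fitted_models(default_cohort):
    """Per-sex, per-part component models fitted on the full default cohort."""
    return fit_models(default_cohort)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic-limit cohort: every measurement/fat noise sd is zero."""
    return generate_cohort(CohortConfig().with_seed(7).noise_free())
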