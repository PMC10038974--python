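import pytest

from solaphen.ratios import compute_ratios
from solaphen.synth_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def big_clean_cohort():
    """Large no-missingness cohort under the default study conditions.

    Shared across model-level checks (threshold performance, parameter
    recovery, emergent concentration moments).
    """
    return generate_cohort(GeneratorConfig(n_patients=100_000, seed=20230101).clean())


@pytest.fixture(scope="session")
def big_clean_ratio_table(big_clean_cohort):
    return compute_ratios(big_clean_cohort)


@pytest.fixture(scope="session")
def lod_cohort():
    """Cohort with the calibrated default limits of detection applied."""
    return generate_cohort(GeneratorConfig(n_patients=50_000, seed=20230102))


@pytest.fixture()
def small_cohort():
    return generate_cohort(GeneratorConfig(n_patients=839, seed=11))
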