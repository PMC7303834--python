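import pytest
from hypothesis import settings

from distreg.synthetic import (
    CohortConfig,
    default_spec,
    generate_cohort,
    pooled_frame,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Three modest sites with all outcomes and heavy event-time ties."""
    sites, truth = generate_cohort(
        CohortConfig(seed=11, site_sizes=(300, 400, 300))
    )
    return sites, truth


@pytest.fixture(scope="session")
def small_sites(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_pool(small_sites):
    return pooled_frame(small_sites)


@pytest.fixture(scope="session")
def specs():
    return {fam: default_spec(fam) for fam in ("linear", "logistic", "cox")}
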