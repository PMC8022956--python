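import pytest
from hypothesis import HealthCheck, settings

import crestmap as cm
from crestmap.synthetic_cohort import default_design, generate_cohort, table1_design

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return cm.build_reference(1)


@pytest.fixture(scope="session")
def alleles(reference):
    return {name: cm.build_allele(reference, name) for name in cm.ALLELE_SPECS}


@pytest.fixture(scope="session")
def wgs_cohort(reference):
    """Default WGS-panel-style cohort: 22 crest samples + 197 controls."""
    return generate_cohort(reference, default_design(), seed=1)


@pytest.fixture(scope="session")
def table1_cohort(reference):
    """Cohort with the published per-breed counts and genotypes."""
    return generate_cohort(reference, table1_design(), seed=1)
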