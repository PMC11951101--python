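import logging

import pytest
from hypothesis import HealthCheck, settings

import bcrpipe as bp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("bcrpipe").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort():
    """One realized default scenario: 8 CD + 7 non-IBD donors, every tissue."""
    return bp.simulate_cohort(seed=7)


@pytest.fixture(scope="session")
def analysis(cohort):
    """Full pipeline run on the session cohort."""
    return bp.analyze_cohort(cohort.airr, cohort.metadata)


def tiny_config(**overrides):
    """A small, fast cohort configuration for replicate-heavy tests:
    CD donors only, terminal ileum only, no expression matrix."""
    base = dict(
        n_donors={"CD": 3, "nonIBD": 0},
        sites_by_group={"CD": ["TI_non_inflamed", "TI_inflamed"]},
        n_clones={
            ("TI_non_inflamed", "MBC"): 40, ("TI_non_inflamed", "PC"): 40,
            ("TI_inflamed", "MBC"): 40, ("TI_inflamed", "PC"): 40,
        },
        emit_expression=False,
    )
    base.update(overrides)
    return bp.CohortConfig(**base)
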