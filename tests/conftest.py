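import pytest
from hypothesis import HealthCheck, settings

import amniotx as ax

settings.register_profile(
    "default", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")

MIXED_EVENTS = {
    "cassette": 0.4,
    "mutually_exclusive": 0.1,
    "alt5": 0.2,
    "alt3": 0.2,
    "intron_retention": 0.1,
}


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene cohort with all five event types planted."""
    cfg = ax.CohortConfig(
        n_genes=300, seed=42, noise_sd=0.3, splice_event_mix=dict(MIXED_EVENTS)
    )
    return ax.generate_cohort(cfg)


@pytest.fixture(scope="session")
def group_design(small_cohort):
    _, _, _, sheet, _ = small_cohort
    return ax.build_design(sheet, ["group", "fetal_sex"], "group")
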