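import numpy as np
import pytest

from piresponse import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort at the emulated study size (n=90)."""
    return generate_cohort(SyntheticCohortConfig(n=90, seed=20))


@pytest.fixture(scope="session")
def default_metrics(default_cohort):
    from piresponse import cohort_metrics
    return cohort_metrics(default_cohort)


def null_config(n: int, seed: int) -> SyntheticCohortConfig:
    """Generator configuration with every planted effect zeroed."""
    from dataclasses import replace
    return replace(
        SyntheticCohortConfig(n=n, seed=seed),
        effect_cycles_on_response_nodular=0.0,
        effect_cycles_on_response_diffuse=0.0,
        responder_hazard_ratio=1.0,
        mgmt_log_dr_shift=0.0,
    )
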