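"""Shared fixtures: small synthetic cohorts reused across the suite."""

import pytest

from plantsig import CohortSimConfig, simulate_cohort

#: Reduced problem sizes for fast unit testing; the KO panel, habitat split
#: and planted-signal parameters stay at the study defaults.
SLIM = dict(
    mean_genes=1600, sd_genes=120.0, n_core_families=200,
    n_accessory_families=1200, n_markers=3,
    prb_target_per_strain=40, prb_target_other=25,
)


@pytest.fixture(scope="session")
def slim_config() -> CohortSimConfig:
    return CohortSimConfig(seed=11, **SLIM)


@pytest.fixture(scope="session")
def slim_cohort(slim_config):
    return simulate_cohort(slim_config)
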