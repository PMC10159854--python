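import dataclasses

import pytest

from spacerlink import CommunityConfig, simulate_community
from spacerlink.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_config() -> CommunityConfig:
    """The seed-pinned default community: 12 bacteria, 4 archaea, 8 viruses
    (2 designated cross-domain), spacer mutations 0-2, seed 7."""
    return CommunityConfig()


@pytest.fixture(scope="session")
def default_truth(default_config):
    return simulate_community(default_config)


@pytest.fixture(scope="session")
def default_run(default_config):
    """Full pipeline on the default fixture: 30x reads, 2e5 Hi-C pairs at
    2% noise. Shared across end-to-end tests to keep the suite fast."""
    return run_pipeline(
        default_config,
        mean_depth=30.0,
        n_hic_pairs=200_000,
        noise_fraction=0.02,
    )


@pytest.fixture()
def tiny_config() -> CommunityConfig:
    return dataclasses.replace(
        CommunityConfig(),
        n_bacteria=5,
        n_archaea=2,
        n_viruses=4,
        seed=3,
    )
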