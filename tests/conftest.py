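import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dyadsync import DyadSimConfig, FixtureEmbeddingProvider, simulate_cohort


@pytest.fixture(scope="session")
def provider():
    return FixtureEmbeddingProvider(dim=64, seed=0)


@pytest.fixture(scope="session")
def coupled_cohort():
    """Small strongly coupled cohort shared by pipeline-level tests."""
    cfg = DyadSimConfig(
        n_sessions=6,
        gamma_vocal=0.8,
        gamma_lexical=0.8,
        frames_per_turn=(60, 120),
        seed=42,
    )
    return simulate_cohort(cfg)
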