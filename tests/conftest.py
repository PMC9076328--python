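from __future__ import annotations

import numpy as np
import pytest

from elindex.config import PipelineConfig
from elindex.synthdata import SynthSpec, synth_cohort


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Three symmetric subjects, shared across tests that only read it."""
    spec = SynthSpec(n_subjects=3, seed=42)
    recordings, truth = synth_cohort(spec)
    return spec, recordings, truth


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort, default_config):
    from elindex.pipeline import compute_features

    _, recordings, _ = small_cohort
    epoch_df, agg = compute_features(recordings, default_config)
    return epoch_df, agg
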