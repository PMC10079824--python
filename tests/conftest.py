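import numpy as np
import pytest

from svwave.config import PipelineConfig
from svwave.fixtures import planted_motif_dataset, shape_pool, step_template


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """Pipeline defaults scaled to suite-sized pools."""
    return PipelineConfig(
        n_bootstrap=8,
        bootstrap_size=96,
        kmeans_restarts=3,
        consistency_repeats=8,
        consistency_subset=30,
        normalize_mode="profile",
    )


@pytest.fixture(scope="session")
def two_family_pool():
    """Raw 512 bp profiles from step-down and step-up shape families."""
    X, labels = shape_pool(
        [step_template(direction=-1), step_template(direction=+1)],
        n_per_family=40,
        noise_sd=3.0,
        seed=42,
    )
    return X, labels


@pytest.fixture(scope="session")
def del_template_pool():
    """Step-down (deletion-left-breakpoint-like) planted motif pool."""
    return planted_motif_dataset(
        step_template(direction=-1), n_profiles=300, noise_sd=3.0, seed=5
    )
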