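"""Shared fixtures: session-scoped models and a default synthetic run."""

from __future__ import annotations

import numpy as np
import pytest

from quorumscan import pipeline, synthetic_data

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def family_models():
    return pipeline.build_family_models()


@pytest.fixture(scope="session")
def default_run(family_models):
    """Default-config synthetic genome plus a full pipeline result."""
    config = synthetic_data.SimConfig(seed=DEFAULT_SEED)
    bundle, truth = synthetic_data.generate_genome(config)
    result = pipeline.run_pipeline(bundle, models=family_models)
    return config, bundle, truth, result


@pytest.fixture(scope="session")
def small_run(family_models):
    """A small two-family genome for cheaper end-to-end checks."""
    config = synthetic_data.SimConfig(
        seed=5,
        families=("Rap", "NprR"),
        systems_per_family=4,
        n_replicons=1,
        background_genes=4,
    )
    bundle, truth = synthetic_data.generate_genome(config)
    result = pipeline.run_pipeline(bundle, models=family_models)
    return config, bundle, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
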