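import numpy as np
import pytest

from ehecco import (
    GeneratorConfig,
    PipelineConfig,
    WeightedSampleSet,
    dataset_from_synthetic,
    generate_dataset,
)

#: small, fast study conditions for unit tests (full-scale runs live in the
#: acceptance tests)
SMALL_GENERATOR = GeneratorConfig(
    n_classes=3,
    n_subjects=2,
    reps_per_cell=2,
    frame_rate=30.0,
    duration_range=(1.0, 2.0),
    seed=1,
)

SMALL_PIPELINE = PipelineConfig(n_clusters=10, q=3, seed=1, inner_folds=2)


def random_sample_set(rng, n, v, q, uniform_weights=False) -> WeightedSampleSet:
    w = None
    if not uniform_weights:
        w = rng.uniform(0.05, 1.0, n)
        w = w / w.sum()
    return WeightedSampleSet(
        primary=rng.normal(size=(n, v)), latent=rng.normal(size=(n, q)), weights=w
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synth():
    return generate_dataset(SMALL_GENERATOR)


@pytest.fixture(scope="session")
def small_dataset(small_synth):
    return dataset_from_synthetic(small_synth, SMALL_PIPELINE)
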