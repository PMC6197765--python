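import numpy as np
import pytest

from biodfa.features import build_predictors
from biodfa.synthetic import EffectSpec, StudyDesign, generate_dataset, pool_controls


@pytest.fixture(scope="session")
def default_dataset():
    """Reference 30-unit factorial dataset with the planted triple-product
    interaction (seed 0)."""
    return generate_dataset(StudyDesign(), EffectSpec.default(0))


@pytest.fixture(scope="session")
def pooled(default_dataset):
    return pool_controls(default_dataset)


@pytest.fixture(scope="session")
def predictor_matrix(pooled):
    return build_predictors(pooled)


@pytest.fixture(scope="session")
def grouping(pooled):
    return pooled.groups.to_numpy(object)
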