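import numpy as np
import pytest

from hsiderm import (
    HyperparameterSet,
    SplitSpec,
    build_reference_library,
    patient_stratified_split,
    train_classifier,
)
from hsiderm.synthetic import make_dataset


@pytest.fixture(scope="session")
def cohort():
    """Seeded 16-patient synthetic cohort: scenes plus labeled spectra."""
    scenes, labeled = make_dataset(n_patients=16, images_per_patient=1, seed=11)
    return scenes, labeled


@pytest.fixture(scope="session")
def splits(cohort):
    _, labeled = cohort
    return patient_stratified_split(labeled, SplitSpec(seed=0))


@pytest.fixture(scope="session")
def reference_library(splits):
    train, _, _ = splits
    return build_reference_library(train, k_skin=3, seed=0)


@pytest.fixture(scope="session")
def svm_model(splits):
    train, _, _ = splits
    return train_classifier(
        train, HyperparameterSet(classifier="svm_linear"), seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
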