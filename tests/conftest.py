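import warnings

import pytest

from longlie import (GeneratorConfig, build_dataset, generate_study,
                     split_dataset, train_ensemble)

warnings.filterwarnings("ignore", message=".*Maximum iterations.*")


@pytest.fixture(scope="session")
def study_sequences():
    """The full default synthetic study: 320 fall + 150 ADL sequences."""
    return generate_study(GeneratorConfig())


@pytest.fixture(scope="session")
def study_dataset(study_sequences):
    return build_dataset(study_sequences)


@pytest.fixture(scope="session")
def study_split(study_dataset):
    return split_dataset(study_dataset, 0.2, 42)


@pytest.fixture(scope="session")
def trained_ensemble(study_split):
    train, _ = study_split
    model, selection = train_ensemble(train, k=5, seed=42)
    return model, selection


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast pipeline-level unit tests."""
    cfg = GeneratorConfig(n_subjects=2, n_fall_types=4, n_adl_types=4, seed=3)
    return generate_study(cfg)
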