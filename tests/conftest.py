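import numpy as np
import pytest

from mosqopen import (
    ActivationSet,
    OpenMaxConfig,
    SyntheticSpec,
    fit_open_set_model,
    generate_activation_set,
    generate_ood_activations,
)


@pytest.fixture(scope="session")
def study_spec() -> SyntheticSpec:
    """The default well-separated ten-class condition used across tests."""
    return SyntheticSpec(n_classes=10, per_class_n=50, separation=6.0, spread=1.0, seed=0)


@pytest.fixture(scope="session")
def train_set(study_spec) -> ActivationSet:
    return generate_activation_set(study_spec)


@pytest.fixture(scope="session")
def model(train_set):
    return fit_open_set_model(train_set, config=OpenMaxConfig())


@pytest.fixture(scope="session")
def test_known(study_spec) -> ActivationSet:
    import dataclasses

    return generate_activation_set(
        dataclasses.replace(study_spec, per_class_n=10, seed=1)
    )


@pytest.fixture(scope="session")
def test_ood(study_spec) -> ActivationSet:
    return generate_ood_activations(study_spec, 100, composition=(33, 34, 33))
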