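import pytest

from stepce import (
    GeneratorConfig,
    ModelConfig,
    generate_dominant_fixture,
    generate_parameter_set,
    generate_worked_fixture,
)


@pytest.fixture(scope="session")
def config():
    return ModelConfig(seed=7)


@pytest.fixture(scope="session")
def worked():
    """Hand-checkable two-person fixture and its frozen expected outcomes.

    Session-scoped: tests must not mutate it (use ``ps.copy()``).
    """
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def dominant():
    return generate_dominant_fixture()


@pytest.fixture(scope="session")
def synth():
    """Full synthetic 80-stratum cohort."""
    return generate_parameter_set(GeneratorConfig(seed=42))
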