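import pytest
from hypothesis import HealthCheck, settings

from phycomet.completeness import grade_matrix
from phycomet.synthetic import SyntheticConfig, generate_dataset, write_fixture_dir

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dataset():
    """Standard synthetic dataset: 4 classes x 8 assemblies, 200 modules,
    10 planted differential modules."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def graded(dataset):
    return grade_matrix(dataset.modules, dataset.annotations)


@pytest.fixture(scope="session")
def fixture_dir(dataset, tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures")
    write_fixture_dir(dataset, path)
    return path
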