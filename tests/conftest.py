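import pytest

from isotrace import correction, fixtures
from isotrace import io as tio


@pytest.fixture(scope="session")
def huh7():
    """Noise-free two-condition fixture with planted ground truth."""
    return fixtures.make_huh7_like_fixture(seed=7, cv=0.0)


@pytest.fixture(scope="session")
def huh7_paths(huh7, tmp_path_factory):
    return fixtures.write_fixture(huh7, tmp_path_factory.mktemp("huh7"))


@pytest.fixture()
def dataset(huh7, huh7_paths):
    """Fresh uncorrected dataset with groups attached."""
    data = tio.read_uncorrected_csv(huh7_paths["csv"])
    data.set_groups(fixtures.groups_from_spec(huh7.spec))
    return data


@pytest.fixture()
def corrected(dataset):
    return correction.correct_dataset(dataset, correction.TracerSpec("C"))


@pytest.fixture(scope="session")
def toy_map(huh7_paths):
    return tio.read_escher_map(huh7_paths["map"])
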