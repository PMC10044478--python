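import pytest

from beeflca import build_system_fixture
from beeflca.pipeline import evaluate_system


@pytest.fixture(scope="session")
def be_base_farms():
    return build_system_fixture("BE", "base", seed=1)


@pytest.fixture(scope="session")
def be_base_result(be_base_farms):
    return evaluate_system(be_base_farms)


@pytest.fixture(scope="session")
def be_frg_result():
    return evaluate_system(build_system_fixture("BE", "FRG", seed=1))


@pytest.fixture(scope="session")
def ge_base_result():
    return evaluate_system(build_system_fixture("GE", "base", seed=1))
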