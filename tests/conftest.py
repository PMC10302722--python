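import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table2():
    from aqbd import datasets

    return datasets.table2_fixture()


@pytest.fixture(scope="session")
def table3():
    from aqbd import datasets

    return datasets.table3_fixture()


@pytest.fixture(scope="session")
def study_config():
    from aqbd import StudyConfig

    return StudyConfig.default()


@pytest.fixture(scope="session")
def refined_models():
    """Refined response-surface models fitted to the embedded CCD study."""
    from aqbd.simulate import truth_from_table3

    truth, results = truth_from_table3()
    return results


@pytest.fixture(scope="session")
def table3_truth():
    from aqbd.simulate import truth_from_table3

    truth, results = truth_from_table3()
    return truth
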