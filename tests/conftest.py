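import pytest

from pasturecf import calibrate, evaluate_scenarios, load_paper_fixtures, load_reference


@pytest.fixture(scope="session")
def scenarios():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def calib(scenarios):
    return calibrate(scenarios)


@pytest.fixture(scope="session")
def results(scenarios, calib):
    """Full-pipeline results for the five packaged treatments, N0..N80."""
    return evaluate_scenarios(scenarios, calib)


@pytest.fixture(scope="session")
def results_by_id(results):
    return {r.treatment_id: r for r in results}
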