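import pytest

import lineup2ht as l


@pytest.fixture(scope="session")
def exp1_data():
    return l.load_experiment_data("exp1")


@pytest.fixture(scope="session")
def exp2_data():
    return l.load_experiment_data("exp2")


@pytest.fixture(scope="session")
def exp1_spec():
    return l.experiment_model("exp1")


@pytest.fixture(scope="session")
def exp2_spec():
    return l.experiment_model("exp2")


@pytest.fixture(scope="session")
def fast_options():
    """Reduced-start optimizer settings for simulation-heavy tests."""
    return l.FitOptions(n_starts=3, compute_se=False)


@pytest.fixture(scope="session")
def exp1_report():
    return l.run_experiment1()


@pytest.fixture(scope="session")
def exp2_report():
    return l.run_experiment2()


@pytest.fixture(scope="session")
def exp1_base_fit(exp1_spec, exp1_data):
    return l.fit(exp1_spec, exp1_data)


@pytest.fixture(scope="session")
def exp2_base_fit(exp2_spec, exp2_data):
    return l.fit(exp2_spec, exp2_data)
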