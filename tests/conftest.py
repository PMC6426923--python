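import numpy as np
import pytest

from adcontinuum.synthetic import (
    default_gradient_table,
    default_group_specs,
    default_trajectory_scenario,
    generate_dataset,
)


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table()


@pytest.fixture(scope="session")
def scenario():
    return default_trajectory_scenario()


@pytest.fixture(scope="session")
def cohort_data():
    """One default-sized synthetic cohort (151 subjects), fully generated."""
    data, predictors, scenario = generate_dataset(seed=42)
    return data


@pytest.fixture(scope="session")
def recovery_fit():
    """The n=1000 recovery simulation shared by trajectory-accuracy tests."""
    from adcontinuum.svc import SVCModel

    specs = default_group_specs(scale=1000 / 151)
    data, _, _ = generate_dataset(specs, seed=1)
    model = SVCModel.from_dataframe(data)
    return model, model.fit(seed=1)
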