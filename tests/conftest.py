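import numpy as np
import pandas as pd
import pytest

from fmasurv.synthetic import (
    CovariateSpec,
    OutcomeModel,
    CensoringModel,
    SimulationConfig,
    ViolationRates,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240322)


@pytest.fixture
def two_arm_config():
    """Small confounded two-arm simulation used across modules."""
    return SimulationConfig(
        arm_labels=["control", "treated"],
        n_per_arm=500,
        covariate_specs={
            "comorbidity": CovariateSpec("bernoulli", p=0.4),
            "age": CovariateSpec("normal", mean=45.0, sd=10.0),
        },
        propensity_coefficients={"treated": {"comorbidity": 1.2}},
        outcome_model=OutcomeModel(
            family="exponential",
            baseline_rate=0.10,
            coefficients={"comorbidity": 0.7},
            log_hr={"treated": float(np.log(0.7))},
        ),
        censoring=CensoringModel(admin_horizon_years=8.0, rate=0.03),
        t0=3.2,
        seed=11,
    )


@pytest.fixture
def claims_fixture_config():
    """Ten-patient claims bundle with hand-countable rule violations:
    2 low-PDC, 1 under-age, 1 prevalent outcome, 1 enrolment gap."""
    return SimulationConfig(
        arm_labels=["DMF", "TER"],
        n_per_arm=5,
        covariate_specs={
            "age": CovariateSpec("normal", mean=45.0, sd=8.0),
            "sex": CovariateSpec("bernoulli", p=0.7),
        },
        outcome_model=OutcomeModel(family="exponential", baseline_rate=0.05),
        censoring=CensoringModel(admin_horizon_years=6.0),
        seed=4,
        violations=ViolationRates(
            low_pdc=0.2, under_age=0.1, prevalent_outcome=0.1, enrolment_gap=0.1
        ),
    )


def toy_survival_frame():
    return pd.DataFrame(
        {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]}
    )
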