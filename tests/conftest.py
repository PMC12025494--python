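import numpy as np
import pandas as pd
import pytest

import crlandmark as cl


@pytest.fixture(scope="session")
def toy_cohort() -> pd.DataFrame:
    """Five patients with hand-checkable follow-up times."""
    return pd.DataFrame(
        {
            "patient_id": [1, 2, 3, 4, 5],
            "time": [0.5, 1.0, 2.0, 3.0, 7.0],
            "event": [1, 0, 2, 3, 1],
            "x": [0.1, 0.2, 0.3, 0.4, 0.5],
        }
    )


@pytest.fixture(scope="session")
def default_config():
    return cl.default_cohort_config(seed=123)


@pytest.fixture(scope="session")
def small_cohort(default_config) -> pd.DataFrame:
    """600-patient default synthetic cohort shared across tests."""
    return cl.generate_cohort(default_config, 600)


@pytest.fixture(scope="session")
def small_super(small_cohort) -> pd.DataFrame:
    return cl.stack_super_dataset(small_cohort, [1.0, 3.0, 5.0])


@pytest.fixture(scope="session")
def small_forest(small_super):
    return cl.fit_forest(small_super, cl.ForestConfig(ntree=25, seed=7, nodesize=20))


def two_cov_config(seed: int, beta_relapse: float = np.log(2), censor_rate: float = 0.0,
                   n_null: int = 0) -> cl.GeneratorConfig:
    """Minimal generator: one binary signal covariate on the relapse cause,
    optional null covariates, exponential hazards."""
    covs = [cl.CovariateSpec("x1", "binary", prevalence=0.5)]
    for j in range(n_null):
        covs.append(cl.CovariateSpec(f"z{j}", "continuous", location=0.0, scale=1.0))
    return cl.GeneratorConfig(
        covariates=covs,
        log_hr={"relapse": {"x1": beta_relapse}},
        baseline_rate={"relapse": 0.08, "cancer_death": 0.03, "other_death": 0.05},
        censor_rate=censor_rate,
        admin_censor_time=15.0,
        seed=seed,
    )
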