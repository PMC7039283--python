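import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ohsspref import (MNLFit, SimulationConfig, apply_exclusions,
                      build_design, default_coding, default_schema,
                      overall_reference_beta, simulate_study,
                      single_class_population, study_cascade_config)
from ohsspref.mnl import beta_from_dict, coded_labels

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def plan():
    return build_design(default_schema(), seed=0)


@pytest.fixture(scope="session")
def cascade(plan):
    """Deterministic study-conditions round: 120 -> 95 -> 92 -> 91."""
    dataset, _ = simulate_study(plan=plan, config=study_cascade_config(seed=0),
                                seed=0)
    analysis, log = apply_exclusions(dataset, plan)
    return dataset, analysis, log


@pytest.fixture(scope="session")
def recovery_small(plan):
    """Single-class simulation, 800 fully responding respondents."""
    config = SimulationConfig(n_invited=800, response_rate=1.0,
                              incomplete_rate=0.0, careless_rate=0.0, seed=11)
    dataset, _ = simulate_study(n=800, plan=plan,
                                pop_model=single_class_population(),
                                config=config, seed=11)
    analysis, _ = apply_exclusions(dataset, plan)
    return analysis


@pytest.fixture(scope="session")
def reference_fit(schema):
    """An MNLFit carrying the published pooled coefficients, zero covariance."""
    coding = default_coding(schema)
    beta = beta_from_dict(overall_reference_beta(), schema, coding)
    labels = coded_labels(schema, coding)
    return MNLFit(labels=labels, beta=beta,
                  covariance=np.zeros((len(beta), len(beta))),
                  loglik=0.0, null_loglik=0.0, n_obs=0, n_params=len(beta),
                  converged=True, coding=coding)
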