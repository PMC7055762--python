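import numpy as np
import pytest

from landboost.synthetic import ScenarioConfig, generate_cohort


def small_scenario(**overrides) -> ScenarioConfig:
    """A fast desk-scale scenario with moderate signal."""
    base = dict(
        n_patients=250,
        n_landmarks=3,
        n_features_per_domain={"diagnoses": 2, "laboratory": 2},
        feature_sparsity=0.7,
        effect_vector_by_landmark={t: (0.8, -0.7, 0.9, 0.6) for t in range(3)},
        baseline_hazard_by_landmark=(0.2, 0.22, 0.25),
        outcome_na_rate=0.1,
        dropout_rate_per_year=0.05,
        seed=11,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One small generated cohort shared by read-only tests."""
    events, truth = generate_cohort(small_scenario())
    return events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
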