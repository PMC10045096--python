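import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gaitdx import (  # noqa: E402
    CohortSpec,
    generate_cohort,
    paper_like_effects,
    preprocess_cohort,
)


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down cohort spec for fast unit tests (not the study-size
    conditions used in the acceptance suite)."""
    return CohortSpec(
        n_acld=8, n_control_subjects=4, trials_per_subject=3, samples_per_trial=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    import dataclasses

    spec = dataclasses.replace(small_spec)
    spec.effects = paper_like_effects(spec, d=1.5)
    return preprocess_cohort(generate_cohort(spec))


@pytest.fixture(scope="session")
def study_cohort():
    """Study-size two-group cohort (25 ACLD vs 9x2 control legs, 5 trials)
    with the paper-like effect preset."""
    spec = CohortSpec(seed=5)
    spec.effects = paper_like_effects(spec, d=1.2)
    return preprocess_cohort(generate_cohort(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
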