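import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fibrosurv as fs

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_slide() -> fs.SyntheticSlide:
    """0.25 mm^2 trichrome fragment with 32% planted fibrosis."""
    return fs.generate_fragment(area_mm2=0.25, target_cvf_percent=32.0, seed=5)


@pytest.fixture(scope="session")
def trained_classifier(small_slide) -> fs.LinearBayesClassifier:
    training = fs.sample_training_pixels(small_slide, n_per_class=1000, seed=1)
    return fs.train_classifier(training)


@pytest.fixture(scope="session")
def cohort_524():
    """Default-condition cohort at the study's sample size."""
    return fs.simulate_cohort(fs.CohortSpec(n=524, seed=42))
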