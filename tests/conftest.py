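import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import antbayes as ab

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_comp(name, boundaries, p0, p1, domain=None):
    """Manual binary attribute composition from boundaries and per-class probs."""
    chunks = [
        ab.ExpertiseChunk(
            ab.Interval(float(boundaries[j]), float(boundaries[j + 1]), j),
            (float(p0[j]), float(p1[j])),
        )
        for j in range(len(boundaries) - 1)
    ]
    lo, hi = (boundaries[0], boundaries[-1]) if domain is None else domain
    return ab.AttributeComposition(name, float(lo), float(hi), chunks)


def make_model(comps, priors=(0.5, 0.5), labels=(0, 1), discrete=()):
    """Manual binary classifier from attribute compositions."""
    return ab.NaiveBayesClassifier(
        list(labels), list(priors), list(comps), list(discrete)
    )


@pytest.fixture(scope="session")
def cohort():
    """Small imbalanced cohort with one informative and one noise attribute."""
    specs = [ab.continuous_spec("marker", separation=2.0), ab.continuous_spec("noise0")]
    return ab.generate_dataset(ab.CohortConfig(400, 0.4, specs, seed=11))


@pytest.fixture(scope="session")
def pool(cohort):
    return ab.generate_expert_pool(cohort, n_subsets=5, top_m=4, seed=7)
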