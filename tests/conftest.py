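import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_cohort():
    """Small default synthetic cohort shared across tests (seeded)."""
    from spise.cohort import default_config, generate_cohort
    return generate_cohort(default_config(seed=11, n_total=900, n_male=476))


@pytest.fixture(scope="session")
def scored(small_cohort):
    from spise.indices import score_cohort
    from spise.mets import classify_cohort
    cohort = small_cohort.data
    panels = score_cohort(cohort)
    profiles = classify_cohort(cohort)
    return cohort, panels, profiles


def random_roc_instance(rng, n_max=200):
    """Random scores/labels with both classes present and ties likely."""
    n = rng.integers(4, n_max + 1)
    if rng.random() < 0.5:
        scores = rng.integers(0, 12, size=n).astype(float)  # heavy ties
    else:
        scores = np.round(rng.normal(size=n), 2)
    labels = rng.random(n) < rng.uniform(0.2, 0.8)
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    return scores, labels
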