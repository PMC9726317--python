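import numpy as np
import pytest

from sbtriage.cea import CeaParameters
from sbtriage.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def base_params():
    return CeaParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def labelled_cohort():
    """A moderate group-conditional cohort with outcome labels."""
    return generate_cohort(SyntheticCohortSpec(mode="group", n=400, seed=11))


def random_scores_labels(rng, n=None):
    """A random score/label fixture with both classes present."""
    if n is None:
        n = int(rng.integers(2, 51))
    n_pos = int(rng.integers(1, n))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    # occasional ties via rounding
    scores = np.round(rng.normal(size=n) + labels * rng.uniform(0, 2), 1)
    return scores, labels
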