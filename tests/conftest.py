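import numpy as np
import pytest

from courtseq.simulate import FIXTURE_SEED, StudyConfig, simulate_study


@pytest.fixture(scope="session")
def fixture_study():
    """The small versioned synthetic study used across the suite."""
    trials, truth = simulate_study(StudyConfig(), seed=FIXTURE_SEED)
    return trials, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)


def random_symbols(rng, n, n_labels=3):
    """Random label sequence over the first ``n_labels`` alphabet symbols."""
    from courtseq.events import ALPHABET

    labels = ALPHABET[:n_labels]
    return [labels[i] for i in rng.integers(0, n_labels, size=n)]
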