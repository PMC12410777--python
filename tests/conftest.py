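import numpy as np
import pytest

from anxsig.synth import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Four participants, 30 s — the smallest valid cohort (one epoch)."""
    return generate_cohort(CohortSpec(n_participants=4, duration_s=30,
                                      seed=7))


@pytest.fixture(scope="session")
def long_recording():
    """One full-length (300 s) synthetic participant for contract tests."""
    recs = generate_cohort(CohortSpec(n_participants=4, duration_s=300,
                                      seed=11))
    return recs[0]
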