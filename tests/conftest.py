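import numpy as np
import pytest

from thermaffect import (
    EMOTIONS,
    FacePhantom,
    default_signatures,
    generate_cohort,
)
from thermaffect.pipeline import preprocess_cohort
from thermaffect.synthetic import CohortConfig


@pytest.fixture(scope="session")
def phantom():
    return FacePhantom()


@pytest.fixture(scope="session")
def signatures():
    return default_signatures(jitter_sd=0.1)


@pytest.fixture(scope="session")
def clean_signatures():
    """Noise-free signatures: deterministic per-region deltas."""
    return default_signatures(jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects per class, default motion/noise; used by several suites."""
    config = CohortConfig(n_per_class={e: 12 for e in EMOTIONS})
    records, manifest = generate_cohort(config, seed=1234)
    return records, manifest


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    records, _ = small_cohort
    return preprocess_cohort(records, register=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
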