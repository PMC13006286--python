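"""Shared fixtures.

The heavyweight multi-seed study and the 10-class benchmark are computed
once per session and shared by the acceptance tests and the module tests
that assert on the same runs.
"""

import numpy as np
import pytest

from microfscil.studies import run_scaled_study, run_tenclass_benchmark

STUDY_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def scaled_study():
    """Three-seed scaled-down comparison study (full vs ablated, mining vs
    plain) on the 10-class / 6-base / 2-way 2-shot synthetic protocol."""
    return run_scaled_study(STUDY_SEEDS)


@pytest.fixture(scope="session")
def tenclass_accuracy():
    """Held-out accuracy of plain 20-epoch training on all 10 synthetic
    classes (chance 0.1)."""
    return run_tenclass_benchmark(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
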