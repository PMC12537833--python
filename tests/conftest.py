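"""Shared fixtures: small seeded synthetic cohorts, all generated in-memory."""

import numpy as np
import pytest

from cravemap import SyntheticConfig, apply_exclusions, generate_cohort


SMALL_CFG = dict(
    n_subjects=14,
    n_excluded=2,
    n_voxels=512,
    signature_support=32,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort_truth():
    """14 subjects on an 8^3 grid; fast enough for per-test reuse."""
    return generate_cohort(SyntheticConfig(**SMALL_CFG))


@pytest.fixture(scope="session")
def small_cohort(small_cohort_truth):
    cohort, truth = small_cohort_truth
    return apply_exclusions(cohort, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
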