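import numpy as np
import pytest

from pnespipe import (
    CohortSpec,
    WelchConfig,
    default_profiles,
    epoch,
    generate_cohort,
)
from pnespipe.spectral import build_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """3+3 subjects x 10 epochs with a strong alpha contrast: fast, separable."""
    cnt, pnes = default_profiles(alpha_ratio=3.0, subject_sd=0.05)
    spec = CohortSpec(n_per_class=3, n_epochs=10, seed=99)
    return generate_cohort(cnt, pnes, spec), spec


@pytest.fixture(scope="session")
def small_table(small_cohort):
    recordings, spec = small_cohort
    sets = [epoch(r, spec.epoch_len_s, max_epochs=spec.n_epochs)
            for r in recordings]
    return build_feature_table(sets, WelchConfig())
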