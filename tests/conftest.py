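import numpy as np
import pytest

from rfqus import (
    CohortSpec,
    PhantomSpec,
    ROIRect,
    extract_cohort_features,
    simulate_cohort,
    simulate_rf,
)
from rfqus.phantom import ClassParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_stack():
    """One modest speckle stack used by several unit tests."""
    return simulate_rf(PhantomSpec(seed=11, n_axial=512, n_beams=24, n_frames=4))


@pytest.fixture(scope="session")
def small_roi():
    return ROIRect(row0=64, col0=4, height=320, width=16)


def small_cohort_spec(maker, n_per_class=5, master_seed=21):
    """Separable/null cohorts shrunk for unit-test speed."""
    return maker(
        n_per_class=n_per_class,
        master_seed=master_seed,
        template=PhantomSpec(n_axial=512, n_beams=24, n_frames=4),
        roi=ROIRect(row0=64, col0=4, height=320, width=16),
    )


@pytest.fixture(scope="session")
def small_separated_table():
    spec = small_cohort_spec(CohortSpec.separated_cohort)
    return extract_cohort_features(simulate_cohort(spec))


@pytest.fixture(scope="session")
def small_cohort():
    spec = small_cohort_spec(CohortSpec.separated_cohort, n_per_class=3, master_seed=5)
    return simulate_cohort(spec)
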