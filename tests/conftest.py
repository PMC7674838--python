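import numpy as np
import pytest

from mriens import (
    CVPlan,
    SyntheticCohortSpec,
    Volume,
    labels_as_int,
    make_cohort,
)


@pytest.fixture(scope="session")
def small_shape():
    return (16, 20, 16)


@pytest.fixture(scope="session")
def small_null_cohort(small_shape):
    """Zero-effect cohort: classes exchangeable by construction."""
    spec = SyntheticCohortSpec(
        shape=small_shape, n_per_class=8, effect_size=0.0, seed=301
    )
    volumes, manifest, mask = make_cohort(spec)
    return volumes, labels_as_int(volumes, spec), mask, spec


@pytest.fixture(scope="session")
def small_effect_cohort(small_shape):
    """Strong inner-localized effect cohort (d = 0.3)."""
    spec = SyntheticCohortSpec(
        shape=small_shape, n_per_class=8, effect_size=0.3, seed=302
    )
    volumes, manifest, mask = make_cohort(spec)
    return volumes, labels_as_int(volumes, spec), mask, spec


@pytest.fixture(scope="session")
def small_plan():
    return CVPlan(k_out=4, k_in=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_volume(shape, seed=0, subject_id="v"):
    rng = np.random.default_rng(seed)
    return Volume(voxels=rng.uniform(size=shape), subject_id=subject_id)
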