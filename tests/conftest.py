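import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from hubdrs import (
    CohortConfig,
    ConnectivityMatrix,
    EpochSpec,
    RunConfig,
    build_atlas,
)
from hubdrs.connectivity import KIND_EPOCH_MEAN


@pytest.fixture
def atlas4():
    return build_atlas(4)


@pytest.fixture
def atlas10():
    return build_atlas(10)


@pytest.fixture
def fast_config():
    """Desk-scale cohort: default effect sizes, 10 s recordings."""
    return CohortConfig(record_minutes=10 / 60)


@pytest.fixture
def fast_run_config(fast_config):
    return RunConfig(
        cohort=fast_config,
        epochs=EpochSpec(n_epochs=1, epoch_seconds=10.0, min_gap_seconds=0.0),
    )


def random_epoch_mean(atlas, rng, masked=False):
    """Random symmetric unit-diagonal correlation-like matrix."""
    n = atlas.n_regions
    a = rng.uniform(-0.9, 0.9, size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 1.0)
    fc = ConnectivityMatrix(values=m, atlas=atlas, kind=KIND_EPOCH_MEAN)
    if masked:
        from hubdrs import drop_interhemispheric

        fc = drop_interhemispheric(fc)
    return fc


def brute_force_drs(removed, spared):
    """Pair-enumeration oracle for the removed-vs-spared statistic."""
    total = 0.0
    for r in removed:
        for s in spared:
            if s > r:
                total += 1.0
            elif s == r:
                total += 0.5
    return total / (len(removed) * len(spared))
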