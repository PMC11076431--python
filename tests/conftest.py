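import numpy as np
import pytest

from ufdce.relaxometry import ConcentrationSeries
from ufdce.simulate import AcquisitionParams, CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def study():
    """Small seeded cohort shared by read-only tests."""
    return simulate_cohort(CohortSpec(n_benign=8, n_malignant=12, seed=7))


@pytest.fixture(scope="session")
def full_study():
    """Default-size cohort (55 benign + 96 malignant), seeded."""
    return simulate_cohort(CohortSpec(seed=11))


def make_series(values, acq: AcquisitionParams | None = None) -> ConcentrationSeries:
    acq = acq or AcquisitionParams()
    values = np.asarray(values, dtype=float)
    return ConcentrationSeries(acq.post_times()[: values.size], values, "L1")


@pytest.fixture(scope="session")
def ramp_curve(acq):
    """C(t) = k t sampled at the post-contrast timestamps, k = 0.01."""
    k = 0.01
    return k, make_series(k * acq.post_times(), acq)
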