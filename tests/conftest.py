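import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_series(data, tr=2.0, mask=None, affine=None):
    """Convenience BoldSeries constructor for tests."""
    from parcelstack.bold import BoldSeries

    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return BoldSeries(data, tr, mask, affine)


@pytest.fixture()
def tiny_cohort():
    """A very small synthetic cohort shared by pipeline-level tests."""
    from parcelstack.synthetic import generate_cohort, planted_cohort_spec

    spec = planted_cohort_spec(seed=42, n_patients=6, n_controls=6)
    return generate_cohort(spec)
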