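import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_rod():
    """A 100 nm straight rod of radius 16 nm with its docking sites."""
    from fluoropaint.simdata import SegmentGroundTruth

    return SegmentGroundTruth(np.array([[0.0, 0.0], [100.0, 0.0]]), 16.0, 48)


def sample_rod_locs(seg, n, precision_nm, rng):
    """Localizations on a rod: uniform over the projection + Gaussian error."""
    from fluoropaint.simdata import _sample_on_projection

    sites = _sample_on_projection(seg, seg.n_docking_sites, rng)
    idx = rng.integers(0, seg.n_docking_sites, n)
    return sites[idx] + rng.normal(0, precision_nm, (n, 2))
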