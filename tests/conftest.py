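import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from summr.harmonize import Action, HarmonizedInstrument

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_instruments(x, y, sy, sx=None, ids=None):
    """Build a harmonised instrument list from plain arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), x.shape)
    sx = (np.full_like(x, 1e-8) if sx is None
          else np.broadcast_to(np.asarray(sx, dtype=float), x.shape))
    ids = ids or [f"rs{i:04d}" for i in range(len(x))]
    return [
        HarmonizedInstrument(snp_id=i, x=float(a), sigma_x=float(b),
                             y=float(c), sigma_y=float(d), action=Action.KEPT_AS_IS)
        for i, a, b, c, d in zip(ids, x, sx, y, sy)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20180205)


@pytest.fixture
def random_instruments(rng):
    """A moderately sized random instrument set with both error sources."""
    k = 10
    x = rng.uniform(0.02, 0.10, k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.02, 0.08, k)
    y = rng.normal(0.3 * x, sy)
    return make_instruments(x, y, sy, sx)
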