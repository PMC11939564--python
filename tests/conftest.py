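import numpy as np
import pytest

from radarbp.config import PrepConfig, SimConfig
from radarbp.simulate import simulate_cohort, simulate_subject


@pytest.fixture(scope="session")
def noise_free_record():
    """60 s noise-free recording with fixed HR and no BP drift."""
    cfg = SimConfig(duration_s=60.0, seed=11, noise_sd=0.0,
                    bp_drift_sd=0.0, hr_range=(60.0, 60.0))
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def drifting_record():
    """120 s noise-free recording with drifting BP (labels vary)."""
    cfg = SimConfig(duration_s=120.0, seed=5, noise_sd=0.0)
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(3, SimConfig(duration_s=60.0), seed=42)


@pytest.fixture()
def prep_nog():
    """Preprocessing config without edge guard (full-record tiling)."""
    return PrepConfig(guard_s=0.0)


def numgrad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f() w.r.t. array x (in place)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g
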