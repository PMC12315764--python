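import numpy as np
import pytest

from hybridqmt.spin_model import QMTParams, default_schedule
from hybridqmt.lineshape import get_default_interpolator


@pytest.fixture(scope="session")
def schedule():
    """Compact hybrid-state schedule used throughout the suite."""
    return default_schedule(n_reps=64, cycle_s=3.5, seed=3)


@pytest.fixture(scope="session")
def midrange_params():
    return QMTParams(m0s=0.15, R1f=0.5, R2f=15.0, Rx=40.0, R1s=2.5, T2s=10e-6)


@pytest.fixture(scope="session", autouse=True)
def _warm_interpolator():
    # build the R2s,l spline table once per session so per-test timings are flat
    get_default_interpolator()
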