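import dataclasses

import numpy as np
import pytest

from roifuse.raw_io import RunData, Scan
from roifuse.synth import CE_PROFILE, HILIC_PROFILE

# shortened separation runs keep the suite fast without changing peak
# shapes, jitter, or noise characteristics
FAST_CE = dataclasses.replace(CE_PROFILE, duration=3.0)
FAST_HILIC = dataclasses.replace(HILIC_PROFILE, duration=5.0)


@pytest.fixture
def simple_run() -> RunData:
    """Five scans, two well-separated mass traces, one weak centroid."""
    scans = []
    for i in range(5):
        scans.append(
            Scan(
                time=float(i) * 0.1,
                mz=np.array([100.0, 100.02 + 1e-4 * i, 250.0]),
                intensity=np.array([1e5, 8e4, 1e3]),
            )
        )
    return RunData(scans=scans, group_id="g", replicate_id="r1")


def gaussian_trace(n=101, center=50.0, sigma=4.0, height=1000.0, dt=1.0):
    t = np.arange(n) * dt
    return t, height * np.exp(-0.5 * ((t - center * dt) / (sigma * dt)) ** 2)
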