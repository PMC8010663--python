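import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glucocest.bloch import simulate_zspectrum
from glucocest.gce import TIMEPOINTS, CestSeries
from glucocest.pools import (
    PoolSystem,
    glucose_phantom_system,
    invivo_scheme,
    phantom_scheme,
    water_pool,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_sch():
    return phantom_scheme()


@pytest.fixture(scope="session")
def invivo_sch():
    return invivo_scheme()


@pytest.fixture(scope="session")
def glucose25_spectrum(phantom_sch):
    """25 mM glucose phantom Z-spectrum under the default scheme."""
    return simulate_zspectrum(glucose_phantom_system(25.0, 7.4), phantom_sch)


@pytest.fixture(scope="session")
def water_spectrum(phantom_sch):
    return simulate_zspectrum(PoolSystem(water=water_pool("phantom")), phantom_sch)


@pytest.fixture
def linear_series(invivo_sch):
    """Tiny uniform CestSeries factory with exactly known MTRasym values."""
    from helpers import linear_mtr_stack

    offsets = invivo_sch.offsets_array()
    larmor = invivo_sch.larmor_hz_per_ppm
    grid = (8, 8)

    def build(values_by_timepoint):
        yy, xx = np.mgrid[0:8, 0:8]
        brain = (yy - 3.5) ** 2 + (xx - 3.5) ** 2 <= 9
        rois = {
            "total_brain": brain,
            "hippocampus_L": brain & (xx <= 2),
            "hippocampus_R": brain & (xx >= 5),
        }
        stacks = {
            t: linear_mtr_stack(values_by_timepoint[t], offsets, grid, larmor)
            for t, _ in TIMEPOINTS
        }
        s0 = {t: np.ones(grid) for t, _ in TIMEPOINTS}
        return CestSeries(
            stacks=stacks,
            s0_images=s0,
            offsets_hz=offsets,
            rois=rois,
            larmor_hz_per_ppm=larmor,
        )

    return build
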