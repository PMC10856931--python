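import numpy as np
import pytest

import fibredose as fd


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture(scope="session")
def hdr_source():
    return fd.example_hdr_source()


@pytest.fixture(scope="session")
def ldr_source():
    return fd.example_ldr_source()


@pytest.fixture(scope="session")
def hdr_series_ideal(hdr_source):
    """HDR bench scan at 1.5 p.e. with no dead time: model-exact means."""
    spec = fd.DETECTORS["PM1125"]
    cfg = fd.SimConfig(window=0.1, threshold=1.5, dead_time=0.0, seed=101)
    return fd.simulate_source_scan(
        hdr_source, fd.hdr_geometry_grid(), fd.DEFAULT_CONVERSION_HZ, spec, cfg
    )


@pytest.fixture(scope="session")
def hdr_series_default(hdr_source):
    """HDR bench scan under the full study conditions (35 ns dead time)."""
    spec = fd.DETECTORS["PM1125"]
    cfg = fd.SimConfig(window=0.1, threshold=1.5, seed=3)
    return fd.simulate_source_scan(
        hdr_source, fd.hdr_geometry_grid(), fd.DEFAULT_CONVERSION_HZ, spec, cfg
    )


@pytest.fixture(scope="session")
def ldr_series(ldr_source):
    """LDR radial scan at 0.5 p.e. with 0.5 s windows."""
    spec = fd.DETECTORS["S13360-1375"]
    cfg = fd.SimConfig(window=0.5, threshold=0.5, seed=11)
    return fd.simulate_source_scan(
        ldr_source, fd.ldr_geometry_grid(), fd.DEFAULT_LDR_CONVERSION_HZ, spec, cfg
    )
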