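import numpy as np
import pytest

from wmhdti.phantom import PhantomSpec, TractGeometry, make_phantom, simulate_dwi


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default two-bundle phantom with noise switched off, plus its DWI."""
    spec = PhantomSpec(snr_b0=None, seed=11)
    ph = make_phantom(spec)
    acq = simulate_dwi(ph.truth, spec)
    return ph, acq


@pytest.fixture(scope="session")
def straight_bundle():
    """A single 40 mm x-aligned bundle in an FA-0 background."""
    geom = [TractGeometry(name="bundle", shape="straight", axis=0,
                          offset=(20.0, 40.0, 40.0), cross_radius_mm=6.0,
                          length_mm=40.0)]
    spec = PhantomSpec(tract_geometries=geom, snr_b0=None, seed=5)
    ph = make_phantom(spec)
    return ph, spec
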