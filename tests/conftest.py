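import numpy as np
import pandas as pd
import pytest

from alphadosim.phantoms import (PhantomSet, place_without_overlap,
                                 sample_elliptical_phantoms)
from alphadosim.transport import SourceModel, WellGeometry


@pytest.fixture(scope="session")
def source():
    return SourceModel()


@pytest.fixture(scope="session")
def well():
    return WellGeometry()


@pytest.fixture(scope="session")
def small_ellipse_set():
    ps = sample_elliptical_phantoms(300, seed=11)
    return place_without_overlap(ps, seed=12)


def make_vertical_arrivals(n, region_side_mm=4.0, energy_mev=3.0, seed=0):
    """Uniform vertical tracks over the scoring square — the analytic
    reference fluence for Poisson hit statistics."""
    rng = np.random.default_rng(seed)
    half = region_side_mm / 2
    x = rng.uniform(-half, half, n)
    y = rng.uniform(-half, half, n)
    return pd.DataFrame({
        "x_mm": x, "y_mm": y,
        "ux": np.zeros(n), "uy": np.zeros(n), "uz": -np.ones(n),
        "polar_angle_deg": np.zeros(n),
        "energy_MeV": np.full(n, energy_mev),
    })
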