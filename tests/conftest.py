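import numpy as np
import pandas as pd
import pytest

from sealproc.types import DeploymentMetadata, Level, Manufacturer, TDRSeries

T0 = np.datetime64("2015-02-01T00:00:00", "s")


def make_series(
    depths,
    interval=8.0,
    resolution=0.5,
    manufacturer=Manufacturer.WC,
    level=Level.ZOC,
    t0=T0,
):
    depths = np.asarray(depths, float)
    t = t0 + (np.arange(len(depths)) * interval).astype("timedelta64[s]")
    return TDRSeries(
        time=t,
        depth=depths,
        sampling_interval=interval,
        depth_resolution=resolution,
        manufacturer=manufacturer,
        level=level,
    )


def square_dive(depth=400.0, n_desc=25, n_bottom=75, n_asc=25, n_surf=20, interval=8.0):
    """Surface pad, linear descent, flat bottom, linear ascent, surface pad."""
    profile = (
        [0.0] * n_surf
        + list(np.linspace(0, depth, n_desc + 1)[1:])
        + [depth] * n_bottom
        + list(np.linspace(depth, 0, n_asc + 1)[1:-1])
        + [0.0] * n_surf
    )
    return make_series(profile, interval=interval)


@pytest.fixture
def meta():
    return DeploymentMetadata(
        toppid="2015001",
        animal_id="X001",
        colony="ANM",
        departure=np.datetime64("2015-02-01T00:00:00"),
        arrival=np.datetime64("2015-02-09T00:00:00"),
    )


@pytest.fixture(scope="session")
def demo():
    """One fully processed demo deployment, shared across tests."""
    from sealproc.simulate import make_demo_deployment

    bundle, truth = make_demo_deployment(seed=3)
    return bundle, truth


class FlatBathymetry:
    """Synthetic elevation grid: ocean everywhere except cells listed as land."""

    def __init__(self, land_cells=(), lat=None, lon=None):
        self.lat = np.arange(20.0, 60.0, 0.5) if lat is None else lat
        self.lon = np.arange(-160.0, -100.0, 0.5) if lon is None else lon
        self.elevation = np.full((len(self.lat), len(self.lon)), -4000.0)
        for la, lo in land_cells:
            i = int(np.argmin(np.abs(self.lat - la)))
            j = int(np.argmin(np.abs(self.lon - lo)))
            self.elevation[i, j] = 100.0
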