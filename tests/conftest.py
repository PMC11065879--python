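import numpy as np
import pytest

from phenomigrate.prep import GriddedSeries, TemporalGrid
from phenomigrate.series import BANDS, ReflectanceSeries


@pytest.fixture(scope="session")
def grid() -> TemporalGrid:
    return TemporalGrid()


def make_reflectance(times=None, **bands) -> ReflectanceSeries:
    """Constant-band reflectance series for hand-worked index examples."""
    if times is None:
        times = np.array([100.0, 150.0, 200.0])
    n = len(times)
    full = {b: np.full(n, 0.1) for b in BANDS}
    for name, value in bands.items():
        full[name] = np.full(n, float(value))
    return ReflectanceSeries(times=np.asarray(times, float), bands=full)


def gridded(values, grid_=None, name="") -> GriddedSeries:
    g = grid_ or TemporalGrid()
    return GriddedSeries(grid=g, values=np.asarray(values, float), name=name)


@pytest.fixture(scope="session")
def triangular_evi(grid):
    """Symmetric triangle peaking at DOY 205: base 0.1, peak 0.9.

    Mid-amplitude 0.5 is crossed at DOY 150 (up) and 260 (down).
    """
    t = grid.centres
    values = 0.1 + 0.8 * np.clip(1.0 - np.abs(t - 205.0) / 110.0, 0.0, 1.0)
    return GriddedSeries(grid=grid, values=values, name="EVI")


@pytest.fixture(scope="session")
def small_scene():
    """A reduced 4-crop scene shared by the slower integration tests."""
    from phenomigrate.synthetic import simulate_region

    return simulate_region(
        {"soybean": 80, "corn": 80, "rice": 80, "peanut": 80},
        seed=11, n_reference=45,
    )
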