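import numpy as np
import pytest

from humidclim import GridSpec, MonthlyClimatology, gen_monthly_climatology


@pytest.fixture
def toy_seasonal() -> MonthlyClimatology:
    return gen_monthly_climatology("toy-seasonal")


@pytest.fixture
def constant_clim() -> MonthlyClimatology:
    return gen_monthly_climatology("constant", c=10.0, h=0.005)


@pytest.fixture
def small_grid() -> GridSpec:
    """6x8 regional grid at 3 degrees, NW corner (30N, 0E)."""
    return GridSpec(n_rows=6, n_cols=8, lat_step=3.0, lon_step=3.0,
                    lat_origin=30.0, lon_origin=0.0)


def random_climatologies(rng: np.random.Generator, n_cells: int) -> MonthlyClimatology:
    """A multi-cell climatology with independent random cells.

    Temperatures span polar to tropical ranges; humidity triples are sorted
    so hmin <= hmean <= hmax holds by construction.
    """
    n_rows = max(1, n_cells // 40)
    n_cols = n_cells // n_rows
    assert n_rows * n_cols == n_cells
    shape = (12, n_rows, n_cols)
    tmin = rng.uniform(-50.0, 25.0, shape)
    tmax = tmin + rng.uniform(0.0, 25.0, shape)
    h = np.sort(rng.uniform(0.0, 0.03, (3,) + shape), axis=0)
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols, lat_step=0.5, lon_step=0.5,
                    lat_origin=60.0, lon_origin=-20.0)
    return MonthlyClimatology(grid=grid, year=2000, tmin=tmin, tmax=tmax,
                              hmin=h[0], hmean=h[1], hmax=h[2])
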