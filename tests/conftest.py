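import numpy as np
import pandas as pd
import pytest

from stngrad import SectorGrid, sector_center_coords


def grid_from_y(y, shape=None, specimen="S01", marker="TH"):
    """Build a SectorGrid whose sector count matches len(y)."""
    y = np.asarray(y, float)
    if shape is None:
        n = int(round(len(y) ** (1 / 3)))
        assert n ** 3 == len(y), "y length must be a cube or shape given"
        shape = (n, n, n)
    rec = sector_center_coords(shape)
    assert len(rec) == len(y)
    rec["y"] = y
    rec["included"] = True
    return SectorGrid(specimen, marker, shape, rec)


@pytest.fixture
def cube_grid():
    """5x5x5 grid with deterministic smooth intensities."""
    rec = sector_center_coords((5, 5, 5))
    rng = np.random.default_rng(7)
    mu = np.exp(2.0 + 0.8 * rec["x1"] - 0.5 * rec["x2"])
    rec["y"] = rng.poisson(mu).astype(float)
    rec["included"] = True
    return SectorGrid("S01", "TH", (5, 5, 5), rec)


@pytest.fixture
def coords_1000():
    return sector_center_coords((10, 10, 10))[["x1", "x2", "x3"]].to_numpy()
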