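import numpy as np
import pandas as pd
import pytest

from habsuit.geodata import EnvRaster, LocalityTable
from habsuit.synthetic import NicheSpec, gen_env_rasters, gen_localities


@pytest.fixture(scope="session")
def raster_quartet():
    return gen_env_rasters(seed=11)


@pytest.fixture(scope="session")
def niche_fixture(raster_quartet):
    """Niche-driven locality table plus generator ground truth."""
    table, truth = gen_localities(raster_quartet, NicheSpec(), seed=12)
    return table, truth


@pytest.fixture()
def tiny_raster():
    """2x2 grid [[1,2],[3,4]], 1-degree cells, origin (0 E, 2 N)."""
    return EnvRaster(
        code="ALT",
        grid=np.array([[1.0, 2.0], [3.0, 4.0]]),
        west=0.0,
        north=2.0,
        cell_size=1.0,
        nodata=-9999.0,
    )


def make_table(rows):
    """rows: list of (species, lon, lat) tuples."""
    return LocalityTable(
        pd.DataFrame(rows, columns=["species", "lon", "lat"]).assign(
            record_id=[str(i) for i in range(len(rows))]
        )
    )
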