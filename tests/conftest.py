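import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from myelospat.io_model import CellTable, RegionSet


def square(side_um: float, x0: float = 0.0, y0: float = 0.0) -> Polygon:
    return Polygon(
        [(x0, y0), (x0 + side_um, y0), (x0 + side_um, y0 + side_um), (x0, y0 + side_um)]
    )


@pytest.fixture
def unit_square_regions() -> RegionSet:
    """One 1 mm² tumor square, µm coordinates."""
    return RegionSet(sample_id="S1", polygons=[(square(1000.0), "tumor")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def make_cells(sample_id: str, points: np.ndarray, phenotype: str) -> CellTable:
    return CellTable(
        sample_id=sample_id,
        data=pd.DataFrame(
            {"x_um": points[:, 0], "y_um": points[:, 1], "phenotype": phenotype}
        ),
    )
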