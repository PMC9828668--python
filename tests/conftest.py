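import warnings

import numpy as np
import pytest

from spermhelix import synthetic as syn
from spermhelix.geometry import (
    FLAGELLUM_PLUS_MINOR,
    FLAGELLUM_WIDTH,
    MAJOR_AXIS,
    CellRecord,
    GyreMeasurement,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # pipeline stages warn about excluded cells; tests assert on results
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_constant_cell(
    n_gyres: int = 5,
    pitch: float = 2.5,
    flag: float = 0.30,
    minor: float = 0.10,
    major: float = 0.20,
    cell_id: str = "c1",
    species: str = "sp1",
) -> CellRecord:
    """Hand-built cell with constant widths and pitch (closed-form volume)."""
    ms = []
    for g in range(1, n_gyres + 1):
        center = (g - 0.5) * pitch
        for h, off in ((1, -pitch / 4), (2, pitch / 4)):
            z = center + off
            ms.append(GyreMeasurement(cell_id, g, h, FLAGELLUM_WIDTH, flag, z))
            ms.append(
                GyreMeasurement(cell_id, g, h, FLAGELLUM_PLUS_MINOR, flag + minor, z)
            )
        ms.append(GyreMeasurement(cell_id, g, 1, MAJOR_AXIS, major, center))
    return CellRecord(
        cell_id=cell_id,
        species=species,
        family="FamX",
        measurements=ms,
        midpiece_length_um=n_gyres * pitch,
        tail_length_um=20.0,
        nucleus_diameter_um=0.6,
    )


@pytest.fixture(scope="session")
def small_tree():
    return syn.simulate_tree(8, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared by read-only pipeline tests."""
    return syn.generate_dataset(seed=7)
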