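import numpy as np
import pytest

from adaptidose import (
    DisplacementField,
    DoseGrid,
    FractionRecord,
    GridGeometry,
    Prescription,
    SeriesRecord,
    StructureMask,
)

RX = 2.0  # Gy per fraction used throughout the small fixtures


@pytest.fixture
def geom() -> GridGeometry:
    return GridGeometry((12, 12, 12), (2.0, 2.0, 2.0))


@pytest.fixture
def uniform_dose(geom) -> DoseGrid:
    return DoseGrid(np.full(geom.shape, 60.0), geom)


@pytest.fixture
def full_mask(geom) -> StructureMask:
    return StructureMask(np.ones(geom.shape, dtype=bool), geom, "CTV")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230322)


def make_box_series(shift_vox: int = 0, rx: float = RX) -> SeriesRecord:
    """One-fraction series with a box target and near-binary dose.

    The reference dose is ``rx`` inside the reference box and 5% of ``rx``
    outside; the fraction's iCTV is the box shifted by ``shift_vox``
    voxels along the last axis, with the adapted dose re-conformed to it
    and an identity displacement field.
    """
    geom = GridGeometry((16, 16, 16), (2.0, 2.0, 2.0))
    ref_box = np.zeros(geom.shape, dtype=bool)
    ref_box[5:11, 5:11, 2:8] = True
    ref_dose = np.where(ref_box, rx, 0.05 * rx)

    ictv = np.roll(ref_box, shift_vox, axis=2)
    adapted = np.where(ictv, rx, 0.05 * rx)
    fraction = FractionRecord(
        index=1,
        ictv=StructureMask(ictv, geom, "iCTV"),
        scheduled_dose=DoseGrid(ref_dose.copy(), geom),
        adapted_dose=DoseGrid(adapted, geom),
        dvf=DisplacementField.identity(geom),
        delivered_plan="adapted",
        edit_class=0,
    )
    return SeriesRecord(
        reference_ctv=StructureMask(ref_box, geom, "CTV"),
        reference_dose=DoseGrid(ref_dose, geom),
        prescription=Prescription(rx, rx),
        ptv_margin_mm=0.0,
        fractions=[fraction],
        series_id="box",
    )


@pytest.fixture
def box_series_identity() -> SeriesRecord:
    return make_box_series(shift_vox=0)


@pytest.fixture
def box_series_shifted() -> SeriesRecord:
    # 8-voxel (16 mm) shift moves the target wholly outside the high-dose box
    return make_box_series(shift_vox=8)
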