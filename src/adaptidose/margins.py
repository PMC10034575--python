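"""Margin expansion, displacement-field dose mapping, and dose accumulation.

The CTV-to-PTV expansion uses a Euclidean distance transform on the voxel
lattice: a voxel joins the expanded structure iff its center lies within
the margin distance of some source-voxel center, with anisotropic spacing
honored.  Dose accumulation maps each fraction's delivered dose back to
the reference geometry by a pull-back through the fraction's displacement
field (reference point ``x`` receives the fraction dose at ``x + dvf(x)``,
trilinear interpolation) and sums voxel-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    DisplacementField,
    DoseGrid,
    GridGeometry,
    SeriesRecord,
    StructureMask,
    ValidationError,
)

logger = logging.getLogger(__name__)


def expand_margin(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic (in mm) expansion of a structure by ``margin_mm``.

    ``margin_mm = 0`` returns an identical mask.  The result keeps the
    source geometry; the label becomes PTV-like for CTV-like inputs.
    """
    if margin_mm < 0:
        raise ValidationError("margin must be >= 0")
    label = {"CTV": "PTV", "iCTV": "iPTV"}.get(mask.label, mask.label)
    if margin_mm == 0:
        return StructureMask(mask.voxels.copy(), mask.geometry, label)
    # distance from each background voxel center to the nearest structure voxel center
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.geometry.spacing)
    return StructureMask(dist <= margin_mm + 1e-9, mask.geometry, label)


@dataclass
class PullBackResult:
    dose: DoseGrid
    n_out_of_bounds: int


def _map_indices(geom_ref: GridGeometry, dvf: DisplacementField, geom_frac: GridGeometry):
    """Fractional voxel indices in the fraction grid of each mapped reference point."""
    zz, yy, xx = np.meshgrid(*geom_ref.voxel_centers_mm(), indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) + dvf.vectors  # physical mm, storage order
    idx = [
        (pts[..., ax] - geom_frac.origin[ax]) / geom_frac.spacing[ax] for ax in range(3)
    ]
    return idx


def pull_back(
    dose_fraction: DoseGrid,
    dvf: DisplacementField,
    return_counts: bool = False,
) -> DoseGrid | PullBackResult:
    """Map a fraction-frame dose onto the reference grid of ``dvf``.

    ``dose_ref(x) = dose_fraction(x + dvf(x))`` with trilinear
    interpolation; mapped points outside the fraction grid contribute
    0 Gy and are counted (logged as a warning when present).
    """
    geom_ref = dvf.geometry
    idx = _map_indices(geom_ref, dvf, dose_fraction.geometry)
    oob = np.zeros(geom_ref.shape, dtype=bool)
    for ax in range(3):
        oob |= (idx[ax] < 0) | (idx[ax] > dose_fraction.geometry.shape[ax] - 1)
    n_oob = int(oob.sum())
    if n_oob:
        logger.warning("pull_back: %d mapped points outside the fraction grid (0 Gy)", n_oob)
    values = ndimage.map_coordinates(
        dose_fraction.values, np.stack(idx), order=1, mode="constant", cval=0.0
    )
    values[values < 0] = 0.0
    out = DoseGrid(values, geom_ref)
    return PullBackResult(out, n_oob) if return_counts else out


def _resample_geometry(geom: GridGeometry, spacing_mm: float) -> GridGeometry:
    """Reference geometry re-gridded to isotropic ``spacing_mm``, same extent."""
    shape = tuple(
        max(1, int(np.floor(geom.spacing[ax] * (geom.shape[ax] - 1) / spacing_mm)) + 1)
        for ax in range(3)
    )
    return GridGeometry(shape, (spacing_mm,) * 3, geom.origin)


def _resample_field(dvf: DisplacementField, target: GridGeometry) -> DisplacementField:
    src = dvf.geometry
    coords = np.meshgrid(
        *[
            (target.origin[ax] + target.spacing[ax] * np.arange(target.shape[ax])
             - src.origin[ax]) / src.spacing[ax]
            for ax in range(3)
        ],
        indexing="ij",
    )
    stacked = np.stack(coords)
    comps = [
        ndimage.map_coordinates(dvf.vectors[..., c], stacked, order=1, mode="nearest")
        for c in range(3)
    ]
    return DisplacementField(np.stack(comps, axis=-1), target)


@dataclass
class AccumulatedDose:
    """Voxel-wise sum of pulled-back per-fraction doses in reference geometry."""

    grid: DoseGrid
    n_fractions: int
    provenance: list[str] = field(default_factory=list)  # plan used per fraction
    n_out_of_bounds: int = 0

    def __post_init__(self):
        if len(self.provenance) != self.n_fractions:
            raise ValidationError("provenance length must equal n_fractions")


def accumulate(
    series: SeriesRecord,
    plan_choice: str = "as_delivered",
    resample_mm: float | None = None,
) -> AccumulatedDose:
    """Accumulate a series' delivered dose in the reference frame.

    ``plan_choice`` is ``adapted``, ``scheduled`` or ``as_delivered`` (follow
    each fraction's ``delivered_plan``).  ``resample_mm`` re-grids the
    reference geometry to an isotropic resolution (1 mm in the clinical
    workflow this mirrors) before mapping; ``None`` keeps the native grid.
    """
    if plan_choice not in ("adapted", "scheduled", "as_delivered"):
        raise ValidationError(f"unknown plan_choice {plan_choice!r}")
    geom = series.reference_dose.geometry
    if resample_mm is not None:
        geom = _resample_geometry(geom, float(resample_mm))
    total = np.zeros(geom.shape)
    provenance: list[str] = []
    n_oob = 0
    for f in series.fractions:
        plan = f.delivered_plan if plan_choice == "as_delivered" else plan_choice
        if plan == "adapted":
            if f.adapted_dose is None:
                raise ValidationError(
                    f"fraction {f.index} has no adapted dose but plan_choice requires it"
                )
            dose = f.adapted_dose
        else:
            dose = f.scheduled_dose
        dvf = f.dvf if resample_mm is None else _resample_field(f.dvf, geom)
        res = pull_back(dose, dvf, return_counts=True)
        total += res.dose.values
        n_oob += res.n_out_of_bounds
        provenance.append(plan)
    return AccumulatedDose(
        grid=DoseGrid(total, geom),
        n_fractions=series.n_fractions,
        provenance=provenance,
        n_out_of_bounds=n_oob,
    )


def resample_mask(mask: StructureMask, target: GridGeometry) -> StructureMask:
    """Nearest-neighbour resample of a mask onto a target geometry."""
    src = mask.geometry
    coords = np.meshgrid(
        *[
            (target.origin[ax] + target.spacing[ax] * np.arange(target.shape[ax])
             - src.origin[ax]) / src.spacing[ax]
            for ax in range(3)
        ],
        indexing="ij",
    )
    vals = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), np.stack(coords), order=0, mode="constant", cval=0
    )
    return StructureMask(vals.astype(bool), target, mask.label)
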