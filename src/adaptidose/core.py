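"""Core domain types for adaptive-radiotherapy dose evaluation.

All volumetric objects live on regular, axis-aligned grids.  Arrays are
stored in ``(z, y, x)`` index order; ``spacing`` and ``origin`` follow the
same storage order (mm).  Physical coordinates reported to users are
``(x, y, z)`` LPS millimetres of voxel *centers*:
``physical(i, j, k) = origin + (i, j, k) * spacing`` (storage order).

Fraction numbering is 1-based, matching clinical usage; voxel indices are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: tolerance (mm) for deciding that two grids share the same geometry
GRID_TOL = 1e-6

TARGET_LABELS = frozenset({"CTV", "iCTV", "PTV", "iPTV"})
OAR_LABELS = frozenset({"bladder", "rectum"})
VALID_LABELS = TARGET_LABELS | OAR_LABELS | {"other"}

DELIVERED_PLANS = ("adapted", "scheduled")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


def _as_triple(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in np.atleast_1d(np.asarray(v, dtype=float)).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValidationError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a regular grid (storage order z, y, x)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", _as_triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValidationError(f"shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be > 0 on every axis, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers (storage order)."""
        return tuple(
            self.origin[ax] + self.spacing[ax] * np.arange(self.shape[ax], dtype=float)
            for ax in range(3)
        )

    def physical_point_xyz(self, index_zyx: Sequence[int]) -> tuple[float, float, float]:
        """Physical (x, y, z) mm of the center of voxel ``(i, j, k)`` (z, y, x order)."""
        p = [self.origin[ax] + self.spacing[ax] * index_zyx[ax] for ax in range(3)]
        return (p[2], p[1], p[0])

    def same_geometry(self, other: "GridGeometry", tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass
class DoseGrid:
    """A 3-D absorbed-dose distribution (Gy) on a regular grid."""

    values: np.ndarray
    geometry: GridGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValidationError(
                f"dose array shape {self.values.shape} != grid shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("dose values must be >= 0")

    @classmethod
    def build(cls, values, spacing, origin=(0.0, 0.0, 0.0)) -> "DoseGrid":
        values = np.asarray(values, dtype=float)
        return cls(values, GridGeometry(values.shape, spacing, origin))


@dataclass
class StructureMask:
    """A binary voxel set (target volume or organ at risk) on a dose grid."""

    voxels: np.ndarray
    geometry: GridGeometry
    label: str = "other"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.shape != self.geometry.shape:
            raise ValidationError(
                f"mask array shape {self.voxels.shape} != grid shape {self.geometry.shape}"
            )
        if self.label not in VALID_LABELS:
            raise ValidationError(f"unknown structure label {self.label!r}")
        if self.label in TARGET_LABELS and not self.voxels.any():
            raise ValidationError(f"target structure {self.label!r} is empty")

    @classmethod
    def build(cls, voxels, spacing, origin=(0.0, 0.0, 0.0), label="other") -> "StructureMask":
        voxels = np.asarray(voxels).astype(bool)
        return cls(voxels, GridGeometry(voxels.shape, spacing, origin), label)

    @property
    def volume_ml(self) -> float:
        """Structure volume in mL (1 mL = 1000 mm^3)."""
        return float(self.voxels.sum()) * self.geometry.voxel_volume_mm3 / 1000.0

    def check_aligned(self, dose: DoseGrid, context: str = "") -> None:
        if not self.geometry.same_geometry(dose.geometry):
            raise ValidationError(
                f"mask {self.label!r} grid {self.geometry} does not match dose grid "
                f"{dose.geometry}{(' (' + context + ')') if context else ''}"
            )


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacements (mm) on the reference grid.

    Convention: maps a reference-frame point to its corresponding
    fraction-frame point, ``x_fraction = x_reference + dvf(x_reference)``.
    Components are stored in array axis order (z, y, x) in the last
    dimension.
    """

    vectors: np.ndarray
    geometry: GridGeometry

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.geometry.shape + (3,):
            raise ValidationError(
                f"DVF shape {self.vectors.shape} != grid shape {self.geometry.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("displacement field must be finite everywhere")

    @classmethod
    def identity(cls, geometry: GridGeometry) -> "DisplacementField":
        return cls(np.zeros(geometry.shape + (3,)), geometry)


@dataclass
class FractionRecord:
    """One treatment fraction: anatomy of the day plus the two candidate plans.

    ``adapted_dose`` is ``None`` when the fraction was delivered as plain
    IGRT and no adaptive plan exists; a zero dose grid is a legal value and
    therefore never used as an absence marker.
    """

    index: int
    ictv: StructureMask
    scheduled_dose: DoseGrid
    dvf: DisplacementField
    adapted_dose: Optional[DoseGrid] = None
    oars: list[StructureMask] = field(default_factory=list)
    delivered_plan: str = "adapted"
    edit_class: int = 0

    def __post_init__(self):
        self.index = int(self.index)
        if self.index < 1:
            raise ValidationError(f"fraction index must be >= 1, got {self.index}")
        self.edit_class = int(self.edit_class)
        if self.edit_class not in (0, 1, 2, 3):
            raise ValidationError(
                f"edit_class must be in 0..3, got {self.edit_class} (fraction {self.index})"
            )
        if self.delivered_plan not in DELIVERED_PLANS:
            raise ValidationError(f"delivered_plan must be one of {DELIVERED_PLANS}")
        if self.delivered_plan == "adapted" and self.adapted_dose is None:
            raise ValidationError(
                f"fraction {self.index} delivered as adapted but has no adapted dose"
            )
        for m in [self.ictv, *self.oars]:
            m.check_aligned(self.scheduled_dose, f"fraction {self.index}")
        if self.adapted_dose is not None and not self.adapted_dose.geometry.same_geometry(
            self.scheduled_dose.geometry
        ):
            raise ValidationError(f"fraction {self.index}: adapted/scheduled grid mismatch")


@dataclass
class Prescription:
    """Total prescribed dose and dose per fraction (Gy)."""

    total_gy: float
    per_fraction_gy: float

    def __post_init__(self):
        if self.total_gy <= 0 or self.per_fraction_gy <= 0:
            raise ValidationError("prescription doses must be > 0")


@dataclass
class SeriesRecord:
    """An ordered treatment series: reference plan plus per-fraction records."""

    reference_ctv: StructureMask
    reference_dose: DoseGrid
    prescription: Prescription
    ptv_margin_mm: float
    fractions: list[FractionRecord]
    series_id: str = "series"

    def __post_init__(self):
        if self.ptv_margin_mm < 0:
            raise ValidationError("ptv_margin_mm must be >= 0")
        if len(self.fractions) < 1:
            raise ValidationError("a series must contain at least 1 fraction")
        self.reference_ctv.check_aligned(self.reference_dose, "reference")
        indices = [f.index for f in self.fractions]
        if len(set(indices)) != len(indices):
            raise ValidationError(f"fraction indices not unique: {indices}")
        expected = self.prescription.per_fraction_gy * len(self.fractions)
        if abs(expected - self.prescription.total_gy) > 1e-9:
            raise ValidationError(
                f"prescription inconsistent: {self.prescription.per_fraction_gy} Gy x "
                f"{len(self.fractions)} fractions != {self.prescription.total_gy} Gy total"
            )
        ref_geom = self.reference_dose.geometry
        for f in self.fractions:
            if not f.scheduled_dose.geometry.same_geometry(ref_geom):
                raise ValidationError(
                    f"fraction {f.index} grid does not match reference grid"
                )
            if not f.dvf.geometry.same_geometry(ref_geom):
                raise ValidationError(f"fraction {f.index} DVF not on reference grid")

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)
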