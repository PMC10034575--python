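"""Seeded synthetic treatment-series generator.

Emulates the data structure of an online-adaptive pelvic radiotherapy
course so the whole evaluation pipeline runs without clinical data:

* a reference plan — an ellipsoidal CTV, its margin-expanded PTV, and a
  dose that is flat at the fraction prescription inside the PTV with a
  sigmoidal penumbra falling off with Euclidean distance outside;
* per-fraction anatomy — the CTV (and bladder-like / rectum-like organs
  at risk) displaced by a rigid interfractional translation drawn from a
  per-axis normal distribution plus a smooth sinusoidal elastic field;
* a *scheduled* dose, the reference dose fixed in room coordinates while
  the anatomy moves under it (IGRT delivery), and an *adapted* dose,
  re-conformed each day to the deformed CTV with the same planning
  recipe (the daily re-optimization surrogate);
* the displacement field linking reference to fraction geometry, used
  for dose accumulation.

The deformation model is geometric, not biomechanical: it produces
controllable interfractional target motion, which is the phenomenon the
dosimetric analysis measures, and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    DisplacementField,
    DoseGrid,
    FractionRecord,
    GridGeometry,
    Prescription,
    SeriesRecord,
    StructureMask,
    ValidationError,
)
from .io import write_series
from .margins import expand_margin


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm, storage order (z, y, x)."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def contains(self, pts_zyx: np.ndarray) -> np.ndarray:
        """Indicator at physical points, shape (..., 3)."""
        q = np.zeros(pts_zyx.shape[:-1])
        for ax in range(3):
            q += ((pts_zyx[..., ax] - self.center_mm[ax]) / self.semiaxes_mm[ax]) ** 2
        return q <= 1.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic treatment series.

    Defaults give a desk-scale pelvic phantom: a 64^3 grid at 2 mm, a
    ~20 mm-semi-axis target, 2 Gy x 6 fractions, a 4 mm penumbra scale
    (~5%/mm falloff), 4 mm per-axis interfractional translation SD with a
    2 mm elastic component, and a 5 mm CTV-to-PTV margin.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    ctv: Ellipsoid | None = None
    bladder: Ellipsoid | None = None
    rectum: Ellipsoid | None = None
    dose_per_fraction_gy: float = 2.0
    n_fractions: int = 6
    penumbra_mm: float = 4.0
    drift_sd_mm: float = 4.0
    deform_amp_mm: float = 2.0
    margin_mm: float = 5.0
    #: per-class probabilities for the contour-edit grade of each fraction
    edit_probs: tuple[float, float, float, float] = (25 / 60, 22 / 60, 11 / 60, 2 / 60)
    #: probability that a fraction is delivered with the adaptive plan
    p_adapted: float = 45 / 61
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in (*self.spacing_mm, self.penumbra_mm,
                                self.dose_per_fraction_gy)):
            raise ValidationError("lengths and doses must be > 0")
        if self.n_fractions < 1:
            raise ValidationError("n_fractions must be >= 1")
        if self.drift_sd_mm < 0 or self.deform_amp_mm < 0 or self.margin_mm < 0:
            raise ValidationError("drift, deformation and margin must be >= 0")
        if abs(sum(self.edit_probs) - 1.0) > 1e-9:
            raise ValidationError("edit_probs must sum to 1")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.shape, self.spacing_mm)

    def resolved(self) -> "SimConfig":
        """Fill in default anatomy centered in the grid."""
        geom = self.geometry
        extent = [geom.spacing[ax] * (geom.shape[ax] - 1) for ax in range(3)]
        c = [e / 2.0 for e in extent]
        ctv = self.ctv or Ellipsoid((c[0], c[1], c[2]), (16.0, 20.0, 16.0))
        bladder = self.bladder or Ellipsoid((c[0], c[1] + 32.0, c[2]), (16.0, 12.0, 16.0))
        rectum = self.rectum or Ellipsoid((c[0], c[1] - 30.0, c[2]), (28.0, 8.0, 8.0))
        return replace(self, ctv=ctv, bladder=bladder, rectum=rectum)


@dataclass
class ReferenceSkeleton:
    """Reference plan of a synthetic series before fraction sampling."""

    config: SimConfig
    ctv: StructureMask
    ptv: StructureMask
    dose: DoseGrid


def _grid_points(geom: GridGeometry) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*geom.voxel_centers_mm(), indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def _conformal_dose(ptv: StructureMask, rx_gy: float, penumbra_mm: float) -> DoseGrid:
    """Prescription inside the PTV, sigmoidal penumbra outside.

    Outside dose at distance d (mm) from the PTV surface is
    ``rx / (1 + exp(d / penumbra - 3))`` — roughly 95% of the
    prescription at the PTV edge and ~5%/mm falloff at the default 4 mm
    penumbra scale.
    """
    dist = ndimage.distance_transform_edt(~ptv.voxels, sampling=ptv.geometry.spacing)
    values = rx_gy / (1.0 + np.exp(np.minimum(dist / penumbra_mm - 3.0, 50.0)))
    values[ptv.voxels] = rx_gy
    return DoseGrid(values, ptv.geometry)


def make_reference(config: SimConfig) -> ReferenceSkeleton:
    """Build the reference CTV, PTV and conformal reference dose."""
    config = config.resolved()
    geom = config.geometry
    pts = _grid_points(geom)
    ctv = StructureMask(config.ctv.contains(pts), geom, "CTV")
    ptv = expand_margin(ctv, config.margin_mm)
    dose = _conformal_dose(ptv, config.dose_per_fraction_gy, config.penumbra_mm)
    return ReferenceSkeleton(config, ctv, ptv, dose)


def _elastic_field(
    geom: GridGeometry, amp_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth sinusoidal displacement field with random phases, |e| <= amp."""
    if amp_mm == 0:
        return np.zeros(geom.shape + (3,))
    pts = _grid_points(geom)
    extent = [geom.spacing[ax] * (geom.shape[ax] - 1) for ax in range(3)]
    out = np.zeros(geom.shape + (3,))
    for comp in range(3):
        phases = rng.uniform(0, 2 * np.pi, size=3)
        wave = np.ones(geom.shape)
        for ax in range(3):
            wave *= np.sin(2 * np.pi * pts[..., ax] / extent[ax] + phases[ax])
        out[..., comp] = amp_mm * wave
    return out


def sample_fraction(
    ref: ReferenceSkeleton, index: int, rng: np.random.Generator
) -> FractionRecord:
    """Draw one fraction: deformed anatomy, scheduled and adapted doses, DVF."""
    cfg = ref.config
    geom = cfg.geometry
    t = rng.normal(0.0, cfg.drift_sd_mm, size=3)  # rigid translation, mm (z, y, x)
    elastic = _elastic_field(geom, cfg.deform_amp_mm, rng)

    # forward mapping reference -> fraction: phi(x) = x + t + e(x)
    dvf = DisplacementField(elastic + t, geom)

    # anatomy of the day: a fraction-frame point y belongs to a structure iff
    # the (approximately) inverse-mapped point y - t - e(y - t) does at planning
    pts = _grid_points(geom)
    shifted = pts - t
    if cfg.deform_amp_mm > 0:
        inv = shifted.copy()
        for comp in range(3):
            inv[..., comp] -= _sample_field_at(elastic[..., comp], geom, shifted)
    else:
        inv = shifted
    ictv = StructureMask(cfg.ctv.contains(inv), geom, "iCTV")
    oars = []
    for label, shape_fn in (("bladder", cfg.bladder), ("rectum", cfg.rectum)):
        vox = shape_fn.contains(inv)
        if vox.any():
            oars.append(StructureMask(vox, geom, label))

    scheduled = DoseGrid(ref.dose.values.copy(), geom)  # fixed in room coordinates
    iptv = expand_margin(ictv, cfg.margin_mm)
    adapted = _conformal_dose(iptv, cfg.dose_per_fraction_gy, cfg.penumbra_mm)

    edit_class = int(rng.choice(4, p=cfg.edit_probs))
    delivered = "adapted" if rng.random() < cfg.p_adapted else "scheduled"
    return FractionRecord(
        index=index,
        ictv=ictv,
        scheduled_dose=scheduled,
        dvf=dvf,
        adapted_dose=adapted,
        oars=oars,
        delivered_plan=delivered,
        edit_class=edit_class,
    )


def _sample_field_at(values: np.ndarray, geom: GridGeometry, pts: np.ndarray) -> np.ndarray:
    idx = np.stack(
        [(pts[..., ax] - geom.origin[ax]) / geom.spacing[ax] for ax in range(3)]
    )
    return ndimage.map_coordinates(values, idx, order=1, mode="nearest")


def simulate_series(config: SimConfig, series_id: str = "series") -> SeriesRecord:
    """Generate a full synthetic series (deterministic for a given seed)."""
    config = config.resolved()
    rng = np.random.default_rng(config.seed)
    ref = make_reference(config)
    fractions = [
        sample_fraction(ref, i + 1, rng) for i in range(config.n_fractions)
    ]
    return SeriesRecord(
        reference_ctv=ref.ctv,
        reference_dose=ref.dose,
        prescription=Prescription(
            config.dose_per_fraction_gy * config.n_fractions, config.dose_per_fraction_gy
        ),
        ptv_margin_mm=config.margin_mm,
        fractions=fractions,
        series_id=series_id,
    )


def generate_cohort(
    configs: Sequence[SimConfig] | SimConfig,
    seed: int,
    n_series: int = 10,
    out_dir: str | Path | None = None,
) -> tuple[list[SeriesRecord], list[dict]]:
    """Generate a cohort of series with per-series seeds derived from ``seed``.

    Pass one base config (replicated ``n_series`` times) or an explicit
    config list.  When ``out_dir`` is given, each series is written there
    under ``series_XX/`` and the manifest entries record the file layout.
    Returns the series list and a summary table (one dict per series with
    its drift settings and seed).
    """
    if isinstance(configs, SimConfig):
        configs = [configs] * int(n_series)
    if not configs:
        raise ValidationError("need at least one series config")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(configs)) % (2**31)
    series_list, summary = [], []
    for k, (cfg, s) in enumerate(zip(configs, child_seeds), start=1):
        cfg_k = replace(cfg, seed=int(s))
        sid = f"series_{k:02d}"
        sr = simulate_series(cfg_k, series_id=sid)
        entry = {
            "series_id": sid,
            "seed": int(s),
            "n_fractions": cfg_k.n_fractions,
            "drift_sd_mm": cfg_k.drift_sd_mm,
            "deform_amp_mm": cfg_k.deform_amp_mm,
            "margin_mm": cfg_k.margin_mm,
        }
        if out_dir is not None:
            entry["manifest"] = str(write_series(sr, Path(out_dir) / sid))
        series_list.append(sr)
        summary.append(entry)
    return series_list, summary
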