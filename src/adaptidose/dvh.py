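"""Dose-volume histograms and dosimetric endpoint metrics.

The cumulative DVH of a structure gives, for each dose level ``D``, the
fraction of the structure's volume receiving at least ``D``.  Endpoints
derived from it are the standard plan-evaluation quantities:

* ``Dx%`` — the dose received by the hottest x% of the volume (D95, D98,
  D99 probe cold spots in target coverage),
* ``Vx%`` — the percentage of the volume receiving at least x% of the
  prescription (V95, V100),
* the generalized equivalent uniform dose (Niemierko),

      gEUD(a) = ( sum_i v_i * d_i**a ) ** (1/a),

  over DVH bins with fractional volume ``v_i`` and representative dose
  ``d_i``.  Large negative exponents (``a = -20`` for targets here) make
  the gEUD track the coldest part of the target; positive exponents
  (serial organs at risk) emphasize hot spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DoseGrid, StructureMask, ValidationError

#: default DVH bin width as a fraction of the prescription dose
DEFAULT_BIN_FRACTION = 0.001

#: target gEUD exponent used throughout the analysis
TARGET_EXPONENT = -20.0

#: serial-organ exponent used for bladder and rectum (configurable assumption)
OAR_EXPONENT = 8.0


@dataclass
class DVH:
    """Differential + cumulative dose-volume histogram with uniform bins."""

    bin_edges: np.ndarray  # length n+1, Gy
    differential: np.ndarray  # length n, fractional volume per bin, sums to 1
    cumulative: np.ndarray  # length n+1, fraction of volume >= edge
    structure_volume_ml: float

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.differential = np.asarray(self.differential, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if np.any(self.differential < 0):
            raise ValidationError("differential DVH must be non-negative")
        if abs(self.differential.sum() - 1.0) > 1e-9:
            raise ValidationError("differential DVH must sum to 1")
        if np.any(np.diff(self.cumulative) > 1e-12):
            raise ValidationError("cumulative DVH must be non-increasing")

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def min_dose(self) -> float:
        """Lower edge of the coldest occupied bin (Gy)."""
        occ = np.nonzero(self.differential > 0)[0]
        return float(self.bin_edges[occ[0]]) if occ.size else 0.0

    def to_frame(self):
        """Tidy table (dose_gy, diff_volume_fraction, cum_volume_fraction)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "dose_gy": self.bin_edges[:-1],
                "diff_volume_fraction": self.differential,
                "cum_volume_fraction": self.cumulative[:-1],
            }
        )


def _in_structure(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    mask.check_aligned(dose)
    if not mask.voxels.any():
        raise ValidationError(f"empty structure {mask.label!r}")
    return dose.values[mask.voxels]


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width_gy: float) -> DVH:
    """Histogram the in-structure dose into uniform bins of ``bin_width_gy``.

    Bins cover ``[0, max in-structure dose]``; the cumulative curve is
    evaluated at every bin edge (``cumulative[0] == 1``).
    """
    if bin_width_gy <= 0:
        raise ValidationError("bin_width_gy must be > 0")
    vals = _in_structure(dose, mask)
    top = float(vals.max())
    n_bins = max(1, int(np.ceil(top / bin_width_gy + 1e-12)))
    edges = bin_width_gy * np.arange(n_bins + 1, dtype=float)
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, edges[-1]))
    diff = counts / counts.sum()
    # fraction of volume with dose >= each edge; the top edge bounds the max
    cum = np.concatenate([np.cumsum(diff[::-1])[::-1], [0.0]])
    cum[0] = 1.0
    volume_ml = mask.volume_ml
    return DVH(edges, diff, cum, volume_ml)


def dose_at_volume(dvh: DVH, x_percent: float) -> float:
    """Dx%: the largest dose D such that at least x% of the volume gets >= D.

    Linearly interpolated on the cumulative curve between bin edges.
    ``x = 100`` returns the coldest occupied bin edge.
    """
    if not 0 < x_percent <= 100:
        raise ValidationError("x_percent must be in (0, 100]")
    target = x_percent / 100.0
    cum, edges = dvh.cumulative, dvh.bin_edges
    if target >= cum[0]:
        # entire volume only guaranteed above the coldest occupied dose
        return dvh.min_dose
    # cum is non-increasing; walk to the last edge with cum >= target,
    # tolerating float rounding in the cumulative sums
    eps = 1e-9
    idx = int(np.searchsorted(-cum, -(target - eps), side="right")) - 1
    idx = min(idx, len(cum) - 2)
    c0, c1 = cum[idx], cum[idx + 1]
    if c0 <= c1:
        return float(edges[idx])
    frac = min(max((c0 - target) / (c0 - c1), 0.0), 1.0)
    return float(edges[idx] + frac * (edges[idx + 1] - edges[idx]))


def volume_at_dose(dvh: DVH, threshold_gy: float) -> float:
    """Vx: percentage of the structure volume receiving >= ``threshold_gy``."""
    if threshold_gy < 0:
        raise ValidationError("threshold_gy must be >= 0")
    cum, edges = dvh.cumulative, dvh.bin_edges
    if threshold_gy <= edges[0]:
        return 100.0
    if threshold_gy >= edges[-1]:
        return 0.0
    return float(100.0 * np.interp(threshold_gy, edges, cum))


def geud(dvh: DVH, a: float) -> float:
    """Generalized equivalent uniform dose from the differential DVH.

    Computed as ``(sum v_i d_i^a)^(1/a)`` over occupied bins with midpoint
    doses, factoring out the dominant dose so the power sums stay finite
    for exponents up to |a| ~ a few hundred.  A structure containing
    zero-dose voxels has gEUD 0 for any ``a < 0`` (the mathematical
    limit); this degenerate case returns 0 with a warning.
    """
    if a == 0:
        raise ValidationError("gEUD exponent a must be nonzero")
    occ = dvh.differential > 0
    v = dvh.differential[occ]
    d = dvh.bin_midpoints[occ]
    if a < 0 and np.any(d <= 0):
        warnings.warn("structure contains zero-dose voxels; gEUD(a<0) -> 0", stacklevel=2)
        return 0.0
    # factor out the dose that dominates the power mean
    dref = float(d.max()) if a > 0 else float(d[d > 0].min())
    if dref == 0.0:
        return 0.0
    with np.errstate(over="raise"):
        s = np.sum(v * np.power(d / dref, a))
    return float(dref * s ** (1.0 / a))


def geud_from_voxels(dose: DoseGrid, mask: StructureMask, a: float) -> float:
    """Voxel-exact gEUD, bypassing DVH discretization (testing/reference mode)."""
    if a == 0:
        raise ValidationError("gEUD exponent a must be nonzero")
    d = _in_structure(dose, mask)
    if a < 0 and np.any(d <= 0):
        warnings.warn("structure contains zero-dose voxels; gEUD(a<0) -> 0", stacklevel=2)
        return 0.0
    dref = float(d.max()) if a > 0 else float(d.min())
    if dref == 0.0:
        return 0.0
    return float(dref * np.mean(np.power(d / dref, a)) ** (1.0 / a))


def min_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Minimum voxel dose within the structure (Gy)."""
    return float(_in_structure(dose, mask).min())


@dataclass
class EndpointSet:
    """The coverage endpoints evaluated per structure and plan."""

    d95: float
    d98: float
    d99: float
    min_dose: float
    v95: float  # % of structure volume
    v100: float  # % of structure volume
    geud: float
    prescription_gy: float
    exponent: float

    def __post_init__(self):
        eps = 1e-9
        if not (self.min_dose <= self.d99 + eps and self.d99 <= self.d98 + eps
                and self.d98 <= self.d95 + eps):
            raise ValidationError(
                f"endpoint ordering violated: min {self.min_dose}, D99 {self.d99}, "
                f"D98 {self.d98}, D95 {self.d95}"
            )
        if self.v100 > self.v95 + eps:
            raise ValidationError("V100 cannot exceed V95")

    def as_dict(self) -> dict[str, float]:
        return {
            "min_dose": self.min_dose,
            "d95": self.d95,
            "d98": self.d98,
            "d99": self.d99,
            "v95": self.v95,
            "v100": self.v100,
            "geud": self.geud,
        }


def endpoints(
    dose: DoseGrid,
    mask: StructureMask,
    prescription_gy: float,
    a: float = TARGET_EXPONENT,
    bin_width_gy: float | None = None,
) -> EndpointSet:
    """Compute the full endpoint set for one structure under one plan."""
    if bin_width_gy is None:
        bin_width_gy = DEFAULT_BIN_FRACTION * prescription_gy
    dvh = compute_dvh(dose, mask, bin_width_gy)
    dmin = min_dose(dose, mask)
    # Dx% >= min dose holds exactly; clamp away sub-bin interpolation error
    return EndpointSet(
        d95=max(dose_at_volume(dvh, 95.0), dmin),
        d98=max(dose_at_volume(dvh, 98.0), dmin),
        d99=max(dose_at_volume(dvh, 99.0), dmin),
        min_dose=dmin,
        v95=volume_at_dose(dvh, 0.95 * prescription_gy),
        v100=volume_at_dose(dvh, 1.00 * prescription_gy),
        geud=geud(dvh, a),
        prescription_gy=prescription_gy,
        exponent=a,
    )
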