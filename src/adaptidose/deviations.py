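"""Normalized per-fraction deviations from the planning reference.

Every dosimetric characteristic (minimum dose, D95/D98/D99, V95, gEUD) of
a deformed target at fraction *i* is expressed as a percentage deviation
from the same characteristic of the undeformed structure under the
reference plan:

    %char(P_i) = 100 * (char(P_i, deformed structure) - char(ref)) / char(ref)

for the adapted plan A_i and the scheduled plan S_i.  The adaptation gain
is the difference Delta = %char(A_i) - %char(S_i): how much of the
deterioration under the fixed scheduled plan the daily re-plan recovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import SeriesRecord, StructureMask, ValidationError
from .dvh import OAR_EXPONENT, TARGET_EXPONENT, EndpointSet, endpoints
from .margins import expand_margin

CHARACTERISTICS = ("min_dose", "d95", "d98", "d99", "v95", "geud")


def percent_deviation(value_fraction: float, value_reference: float) -> float:
    """Percentage deviation of a per-fraction metric from its reference value."""
    if value_reference <= 0:
        raise ValidationError(f"degenerate reference value {value_reference}")
    return 100.0 * (value_fraction - value_reference) / value_reference


def adaptation_gain(dev_adapted: float, dev_scheduled: float) -> float:
    """Gain of the adaptive over the scheduled plan (percentage points)."""
    return dev_adapted - dev_scheduled


@dataclass
class DeviationRecord:
    fraction_index: int
    structure: str
    characteristic: str
    pct_dev_adapted: float | None
    pct_dev_scheduled: float
    gain: float | None

    def __post_init__(self):
        if self.pct_dev_adapted is not None and self.gain is not None:
            if abs(self.gain - (self.pct_dev_adapted - self.pct_dev_scheduled)) > 1e-9:
                raise ValidationError("gain must equal adapted - scheduled deviation")


def _deviation_rows(
    index: int,
    structure: str,
    ref: EndpointSet,
    sched: EndpointSet,
    adap: EndpointSet | None,
    characteristics: Sequence[str],
) -> list[DeviationRecord]:
    rows = []
    ref_d, sched_d = ref.as_dict(), sched.as_dict()
    adap_d = adap.as_dict() if adap is not None else None
    for char in characteristics:
        dev_s = percent_deviation(sched_d[char], ref_d[char])
        dev_a = percent_deviation(adap_d[char], ref_d[char]) if adap_d else None
        gain = adaptation_gain(dev_a, dev_s) if dev_a is not None else None
        rows.append(DeviationRecord(index, structure, char, dev_a, dev_s, gain))
    return rows


def series_deviations(
    series: SeriesRecord,
    a_target: float = TARGET_EXPONENT,
    a_oar: float = OAR_EXPONENT,
    eval_margin_mm: float | None = None,
    include_oars: bool = True,
    characteristics: Sequence[str] = CHARACTERISTICS,
) -> list[DeviationRecord]:
    """Per-fraction deviation records for a whole series.

    Target metrics are evaluated on each fraction's deformed CTV (and,
    when ``eval_margin_mm`` resolves to > 0, its margin expansion — the
    per-fraction PTV) against that fraction's scheduled and adapted dose
    grids, normalized by the corresponding undeformed structure under the
    reference plan.  OAR records carry gEUD only, with the serial-organ
    exponent.
    """
    margin = series.ptv_margin_mm if eval_margin_mm is None else float(eval_margin_mm)
    rx = series.prescription.per_fraction_gy

    ref_ctv_ep = endpoints(series.reference_dose, series.reference_ctv, rx, a_target)
    ref_ptv_ep = None
    if margin > 0:
        ref_ptv = expand_margin(series.reference_ctv, margin)
        ref_ptv_ep = endpoints(series.reference_dose, ref_ptv, rx, a_target)

    ref_oar_geud: dict[str, float] = {}
    rows: list[DeviationRecord] = []
    for f in series.fractions:
        sched_ep = endpoints(f.scheduled_dose, f.ictv, rx, a_target)
        adap_ep = (
            endpoints(f.adapted_dose, f.ictv, rx, a_target)
            if f.adapted_dose is not None
            else None
        )
        rows += _deviation_rows(f.index, "iCTV", ref_ctv_ep, sched_ep, adap_ep, characteristics)

        if ref_ptv_ep is not None:
            iptv = expand_margin(f.ictv, margin)
            sched_p = endpoints(f.scheduled_dose, iptv, rx, a_target)
            adap_p = (
                endpoints(f.adapted_dose, iptv, rx, a_target)
                if f.adapted_dose is not None
                else None
            )
            rows += _deviation_rows(f.index, "iPTV", ref_ptv_ep, sched_p, adap_p, characteristics)

        if include_oars:
            for oar in f.oars:
                if oar.label not in ref_oar_geud:
                    # reference OAR gEUD from the undeformed organ; the deformed
                    # per-fraction organ stands in when no reference contour exists
                    ref_oar_geud[oar.label] = endpoints(
                        series.reference_dose, _nonempty(oar), rx, a_oar
                    ).geud
                ref_g = ref_oar_geud[oar.label]
                if ref_g <= 0:
                    continue
                sched_g = endpoints(f.scheduled_dose, _nonempty(oar), rx, a_oar).geud
                dev_s = percent_deviation(sched_g, ref_g)
                dev_a = gain = None
                if f.adapted_dose is not None:
                    adap_g = endpoints(f.adapted_dose, _nonempty(oar), rx, a_oar).geud
                    dev_a = percent_deviation(adap_g, ref_g)
                    gain = adaptation_gain(dev_a, dev_s)
                rows.append(DeviationRecord(f.index, oar.label, "geud", dev_a, dev_s, gain))
    return rows


def _nonempty(mask: StructureMask) -> StructureMask:
    if not mask.voxels.any():
        raise ValidationError(f"empty structure {mask.label!r}")
    return mask


def deviations_frame(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    """Tidy table of deviation records (one row per record)."""
    return pd.DataFrame(
        {
            "fraction": [r.fraction_index for r in records],
            "structure": [r.structure for r in records],
            "characteristic": [r.characteristic for r in records],
            "pct_dev_adapted": [r.pct_dev_adapted for r in records],
            "pct_dev_scheduled": [r.pct_dev_scheduled for r in records],
            "gain": [r.gain for r in records],
        }
    )


@dataclass
class DistributionSummary:
    """Median with the empirical 5th-95th percentile range of a deviation set."""

    median: float
    lo90: float
    hi90: float
    n: int

    def __post_init__(self):
        if not (self.lo90 <= self.median <= self.hi90):
            raise ValidationError("percentile ordering violated")


def summarize(values: Sequence[float]) -> DistributionSummary:
    """Median and empirical 5th/95th percentiles (linear interpolation)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty sample")
    lo, med, hi = np.percentile(arr, [5, 50, 95], method="linear")
    return DistributionSummary(float(med), float(lo), float(hi), int(arr.size))


def bootstrap_median_ci(
    values: Sequence[float],
    level: float = 0.90,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the median (alternative
    reading of a 'median with 90% interval' report)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(arr, size=(n_boot, arr.size), replace=True), axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(meds, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def ecdf(values: Sequence[float]) -> Callable[[float], float]:
    """Right-continuous empirical distribution function of a sample."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    if arr.size == 0:
        raise ValidationError("cannot build an ECDF from an empty sample")
    n = arr.size

    def f(x: float) -> float:
        return float(np.searchsorted(arr, x, side="right")) / n

    return f
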