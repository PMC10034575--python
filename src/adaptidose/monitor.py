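"""Offline IGRT-to-ART switching rule and per-series monitoring tallies.

A patient starts on the scheduled (IGRT) plan while the per-fraction
target-coverage deviation %gEUD_iCTV is monitored offline.  A fraction is
a *violation* when its deviation falls strictly below a cutpoint (default
-7%).  The series switches to daily adaptive replanning at the earliest
fraction where either

* the second violation occurs within the early window (first 9
  fractions), or
* beyond the early window, the running proportion of violations among
  all fractions observed so far exceeds 20%.

Evaluation is strictly sequential: fractions after the switch point are
not inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import ValidationError


@dataclass(frozen=True)
class RuleConfig:
    """Parameters of the switching rule."""

    cutpoint_pct: float = -7.0
    early_window: int = 9
    late_proportion: float = 0.20
    #: if True, the late-phase proportion counts violations only among
    #: fractions after the early window instead of all fractions so far
    late_post_window_only: bool = False

    def __post_init__(self):
        if self.cutpoint_pct >= 0:
            raise ValidationError("cutpoint must be negative (a coverage deficit)")
        if self.early_window < 1:
            raise ValidationError("early_window must be >= 1")
        if not 0 < self.late_proportion < 1:
            raise ValidationError("late_proportion must be in (0, 1)")


@dataclass
class SwitchDecision:
    switched: bool
    switch_after_fraction: Optional[int]
    trigger: str  # second_violation_early | proportion_late | none
    violation_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.switched and (self.switch_after_fraction is None or self.trigger == "none"):
            raise ValidationError("a switched decision needs a fraction index and trigger")
        if not self.switched and self.trigger != "none":
            raise ValidationError("an unswitched decision must have trigger 'none'")


def evaluate_switch(
    deviations_pct: Sequence[float], config: RuleConfig = RuleConfig()
) -> SwitchDecision:
    """Apply the switching rule to scheduled-plan %gEUD_iCTV values in
    fraction order.

    Ties between the two triggers at the same fraction report
    ``second_violation_early`` (deterministic reporting).
    """
    devs = list(deviations_pct)
    if not devs:
        raise ValidationError("empty deviation sequence")
    violations: list[int] = []
    for i, dev in enumerate(devs, start=1):
        if dev < config.cutpoint_pct:
            violations.append(i)
        n_viol = len(violations)
        if i <= config.early_window:
            if n_viol >= 2 and violations[1] == i:
                return SwitchDecision(True, i, "second_violation_early", violations.copy())
        else:
            denom = i - config.early_window if config.late_post_window_only else i
            count = (
                sum(1 for v in violations if v > config.early_window)
                if config.late_post_window_only
                else n_viol
            )
            if denom > 0 and count / denom > config.late_proportion:
                return SwitchDecision(True, i, "proportion_late", violations.copy())
    return SwitchDecision(False, None, "none", violations)


def tally_edits(
    edit_classes: Sequence[int], total: Optional[int] = None
) -> dict[int, dict[str, float]]:
    """Counts and percentages of contour-edit classes (0 none … 3 major).

    Percentages are rounded to 1 decimal for reporting; raw counts are
    retained alongside.  ``total`` overrides the denominator when the
    graded list is a subset of the assessed fractions (e.g. fractions with
    no recorded grade).
    """
    classes = list(edit_classes)
    if not classes:
        raise ValidationError("empty series")
    if any(c not in (0, 1, 2, 3) for c in classes):
        raise ValidationError("edit classes must be in 0..3")
    n = total if total is not None else len(classes)
    if n < len(classes):
        raise ValidationError("total cannot be smaller than the graded count")
    out = {}
    for c in (0, 1, 2, 3):
        count = classes.count(c)
        out[c] = {"count": count, "percent": round(100.0 * count / n, 1)}
    return out


def delivered_fraction_share(delivered_plans: Sequence[str]) -> float:
    """Percentage of fractions delivered with the adaptive plan (1 decimal)."""
    plans = list(delivered_plans)
    if not plans:
        raise ValidationError("empty series")
    if any(p not in ("adapted", "scheduled") for p in plans):
        raise ValidationError("delivered plans must be 'adapted' or 'scheduled'")
    return round(100.0 * plans.count("adapted") / len(plans), 1)


@dataclass
class CoverageFlags:
    v100_pass: bool
    d98_pass: bool

    @property
    def both_pass(self) -> bool:
        return self.v100_pass and self.d98_pass


def coverage_check(endpoint_set, prescription_gy: float) -> CoverageFlags:
    """Primary coverage goals: V100% > 95% of volume and D98 > 98% of the
    prescription (both strict)."""
    return CoverageFlags(
        v100_pass=endpoint_set.v100 > 95.0,
        d98_pass=endpoint_set.d98 > 0.98 * prescription_gy,
    )
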