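"""Screening schedule, detection outcomes, and treatment decisions.

Both comparator strategies perform a visual-tactile examination every
cycle and a bitewing radiograph every second cycle.  They differ only in
who reads the radiograph: the dentist alone, or a convolutional network
whose accuracy depends on how much data it was trained on (and which
adds a per-application fee).  Visual-tactile examination can detect only
advanced (D2–D3) lesions; initial lesions (E2, D1) are radiograph-only.

A positive radiographic call on a sound (or arrested) surface is a false
positive and is acted upon: with probability ``fp_advanced_share`` it is
read as an advanced lesion and the tooth is restored — dragging a sound
tooth into the restorative cascade — otherwise it is infiltrated.  This
is the pathway through which imperfect specificity generates harm and
cost.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

import numpy as np

from .markov import CostEvent, HealthState, ToothState
from .parameters import AccuracyProfile, CostTable


class ContractViolationError(ValueError):
    """Detection outcome inconsistent with the tooth's health state."""


class DetectionOutcome(Enum):
    TP_INITIAL = "TP_initial"
    TP_ADVANCED = "TP_advanced"
    FN = "FN"
    TN = "TN"
    FP_INITIAL = "FP_initial"
    FP_ADVANCED = "FP_advanced"
    NOT_EXAMINED = "not_examined"


@dataclass
class Strategy:
    label: str  # "dentist_no_ai" | "dentist_with_ai"
    radiograph_accuracy: AccuracyProfile
    uses_ai_cost: bool = False


@dataclass
class Schedule:
    visual_tactile_every_years: int = 1
    radiograph_every_years: int = 2

    def is_vt_cycle(self, cycle: int) -> bool:
        return cycle % self.visual_tactile_every_years == 0

    def is_radiograph_cycle(self, cycle: int) -> bool:
        return cycle % self.radiograph_every_years == 0


_SCREENABLE = frozenset({HealthState.SOUND, HealthState.ARRESTED})
_INITIAL_LESIONS = frozenset({HealthState.E2, HealthState.D1})


def _examine_core(
    health: HealthState,
    radiograph_acc: AccuracyProfile,
    vt_acc: AccuracyProfile,
    radio_cycle: bool,
    vt_cycle: bool,
    fp_advanced_share: float,
    u_radio: float,
    u_vt: float,
    u_stage: float,
) -> DetectionOutcome:
    if not radio_cycle and not vt_cycle:
        return DetectionOutcome.NOT_EXAMINED
    if health in _SCREENABLE:
        # Arrested surfaces are screened like sound ones and can yield FPs.
        flagged = False
        if radio_cycle and u_radio < 1.0 - radiograph_acc.specificity:
            flagged = True
        if vt_cycle and u_vt < 1.0 - vt_acc.specificity:
            flagged = True
        if flagged:
            if u_stage < fp_advanced_share:
                return DetectionOutcome.FP_ADVANCED
            return DetectionOutcome.FP_INITIAL
        return DetectionOutcome.TN
    if health in _INITIAL_LESIONS:
        if not radio_cycle:
            # visual-tactile cannot see initial lesions (sensitivity 0)
            return DetectionOutcome.FN
        sens = radiograph_acc.sensitivity(health.value)
        return DetectionOutcome.TP_INITIAL if u_radio < sens else DetectionOutcome.FN
    if health is HealthState.D2D3:
        detected = False
        if radio_cycle and u_radio < radiograph_acc.sensitivity("D2D3"):
            detected = True
        if vt_cycle and u_vt < vt_acc.sensitivity("D2D3"):
            detected = True
        return DetectionOutcome.TP_ADVANCED if detected else DetectionOutcome.FN
    # treated or absorbing states are not re-diagnosed
    return DetectionOutcome.NOT_EXAMINED


def examine(
    s: ToothState,
    strat: Strategy,
    sched: Schedule,
    cycle: int,
    acc_vt: AccuracyProfile,
    rng: np.random.Generator,
    fp_advanced_share: float = 0.2,
) -> DetectionOutcome:
    """Screen one tooth at one cycle and classify the finding."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return _examine_core(
        s.health,
        strat.radiograph_accuracy,
        acc_vt,
        sched.is_radiograph_cycle(cycle),
        sched.is_vt_cycle(cycle),
        fp_advanced_share,
        float(rng.random()),
        float(rng.random()),
        float(rng.random()),
    )


def _decide_core(
    s: ToothState, d: DetectionOutcome, costs: CostTable, year: int
) -> list:
    """Apply the treatment decision for detection outcome ``d`` in place."""
    h = s.health
    if d is DetectionOutcome.TP_INITIAL:
        if h not in _INITIAL_LESIONS:
            raise ContractViolationError(f"TP_initial on {h.value}")
        s.health = HealthState.ARRESTED
        return [CostEvent("infiltration", costs.infiltration, year)]
    if d is DetectionOutcome.TP_ADVANCED:
        if h is not HealthState.D2D3:
            raise ContractViolationError(f"TP_advanced on {h.value}")
        s.health = HealthState.RESTORED
        return [CostEvent("composite_restoration", costs.composite_restoration, year)]
    if d is DetectionOutcome.FP_INITIAL:
        if h not in _SCREENABLE:
            raise ContractViolationError(f"FP_initial on {h.value}")
        # needless infiltration; health unchanged
        return [CostEvent("infiltration", costs.infiltration, year)]
    if d is DetectionOutcome.FP_ADVANCED:
        if h not in _SCREENABLE:
            raise ContractViolationError(f"FP_advanced on {h.value}")
        s.health = HealthState.RESTORED
        return [CostEvent("composite_restoration", costs.composite_restoration, year)]
    if d in (DetectionOutcome.FN, DetectionOutcome.TN, DetectionOutcome.NOT_EXAMINED):
        return []
    raise ContractViolationError(f"unknown detection outcome {d}")


def decide_and_treat(s: ToothState, d: DetectionOutcome, costs: CostTable, year: int = 0):
    """Translate a detection outcome into treatment.  Returns (state, events)."""
    out = ToothState(**{f.name: getattr(s, f.name) for f in fields(ToothState)})
    events = _decide_core(out, d, costs, year)
    return out, events


def exam_costs(
    strat: Strategy, sched: Schedule, cycle: int, costs: CostTable
) -> list:
    """Fee events for the examinations scheduled at this cycle."""
    events = []
    if sched.is_vt_cycle(cycle):
        events.append(CostEvent("visual_tactile_exam", costs.visual_tactile_exam, cycle))
    if sched.is_radiograph_cycle(cycle):
        events.append(CostEvent("radiograph_exam", costs.radiograph_exam, cycle))
        if strat.uses_ai_cost:
            events.append(CostEvent("ai_application", costs.ai_application, cycle))
    return events
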