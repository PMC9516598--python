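"""Tooth-level Markov health-state machine.

One posterior tooth with one proximal surface walks through discrete
annual cycles.  Untreated surfaces progress SOUND → E2 → D1 → D2–D3
(one step per cycle at most); an arrested initial lesion may fail back
to D1.  Detected initial lesions are arrested by resin infiltration;
detected advanced lesions enter the restorative cascade:

    composite restoration —(repeated failure)→ crown —(failure)→
    crown replaced once —(failure)→ root canal treatment —(failure)→
    nonsurgical retreatment —(failure)→ surgical retreatment —(failure)→
    extraction + implant-supported crown (absorbing)

Endodontic complications can also arise directly in restored or crowned
teeth, jumping the tooth to root canal treatment.  Each treatment emits
a :class:`CostEvent` in the cycle it occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import CostTable, RiskProfile


class HealthState(Enum):
    SOUND = "SOUND"
    E2 = "E2"
    D1 = "D1"
    D2D3 = "D2D3"
    ARRESTED = "ARRESTED"
    RESTORED = "RESTORED"
    CROWNED = "CROWNED"
    ROOT_FILLED = "ROOT_FILLED"
    RETREATED_NONSURG = "RETREATED_NONSURG"
    RETREATED_SURG = "RETREATED_SURG"
    EXTRACTED_IMPLANT = "EXTRACTED_IMPLANT"


UNTREATED_STATES = frozenset(
    {HealthState.SOUND, HealthState.E2, HealthState.D1, HealthState.D2D3, HealthState.ARRESTED}
)
TREATED_STATES = frozenset(
    {
        HealthState.RESTORED,
        HealthState.CROWNED,
        HealthState.ROOT_FILLED,
        HealthState.RETREATED_NONSURG,
        HealthState.RETREATED_SURG,
    }
)

_INITIAL_STATE_MAP = {
    "sound": HealthState.SOUND,
    "E2": HealthState.E2,
    "D1": HealthState.D1,
    "D2D3": HealthState.D2D3,
}


@dataclass
class ToothState:
    health: HealthState = HealthState.SOUND
    restoration_failures: int = 0
    crown_replaced: bool = False
    age_years: int = 0
    alive_tooth: bool = True


@dataclass
class TransitionTable:
    """Annual transition probabilities of the state machine.

    ``restoration_failures_before_crown`` is the number of restoration
    failures after which a crown is placed instead of another repair or
    replacement; ``p_repair`` is the probability that a non-terminal
    restoration failure is resolved by repair rather than replacement.
    """

    p_sound_to_E2: float = 0.0
    p_E2_to_D1: float = 0.0
    p_D1_to_D2D3: float = 0.0
    p_arrest_failure: float = 0.0
    p_restoration_failure: float = 0.0
    p_crown_failure: float = 0.0
    p_endo_complication: float = 0.0
    p_rootfill_failure: float = 0.0
    p_retreat_failure: float = 0.0
    p_surg_retreat_failure: float = 0.0
    restoration_failures_before_crown: int = 3
    p_repair: float = 0.5

    PROBABILITY_FIELDS = (
        "p_sound_to_E2",
        "p_E2_to_D1",
        "p_D1_to_D2D3",
        "p_arrest_failure",
        "p_restoration_failure",
        "p_crown_failure",
        "p_endo_complication",
        "p_rootfill_failure",
        "p_retreat_failure",
        "p_surg_retreat_failure",
        "p_repair",
    )

    def violations(self) -> list:
        out = []
        for name in self.PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                out.append(f"transitions.{name} = {v} outside [0, 1]")
        if self.restoration_failures_before_crown < 1:
            out.append(
                "transitions.restoration_failures_before_crown = "
                f"{self.restoration_failures_before_crown} must be >= 1"
            )
        return out


@dataclass
class CostEvent:
    label: str
    euros: float
    year: int


def initial_state(risk: "RiskProfile", rng: np.random.Generator) -> ToothState:
    """Draw a tooth's starting state from the risk profile's prevalence."""
    labels = list(risk.initial_state_prevalence)
    probs = np.array([risk.initial_state_prevalence[s] for s in labels], dtype=float)
    idx = int(rng.choice(len(labels), p=probs / probs.sum()))
    return ToothState(health=_INITIAL_STATE_MAP[labels[idx]])


# -- core single-draw logic (shared by the public API and the simulator) --


def _natural_core(s: ToothState, t: TransitionTable, u: float) -> None:
    """Apply at most one disease transition, driven by uniform draw ``u``."""
    h = s.health
    if h is HealthState.SOUND:
        if u < t.p_sound_to_E2:
            s.health = HealthState.E2
    elif h is HealthState.E2:
        if u < t.p_E2_to_D1:
            s.health = HealthState.D1
    elif h is HealthState.D1:
        if u < t.p_D1_to_D2D3:
            s.health = HealthState.D2D3
    elif h is HealthState.ARRESTED:
        if u < t.p_arrest_failure:
            s.health = HealthState.D1


def _treatment_core(
    s: ToothState,
    t: TransitionTable,
    costs: "CostTable",
    year: int,
    u_endo: float,
    u_fail: float,
    u_repair: float,
) -> list:
    """One annual cycle of failure/complication hazards in a treated state.

    Returns the cost events emitted this cycle and mutates ``s`` in place.
    An endodontic complication (restored or crowned teeth only) preempts
    the same-cycle failure draw.
    """
    events = []
    h = s.health
    if h in (HealthState.RESTORED, HealthState.CROWNED) and u_endo < t.p_endo_complication:
        s.health = HealthState.ROOT_FILLED
        events.append(CostEvent("root_canal_treatment", costs.root_canal_treatment, year))
        return events
    if h is HealthState.RESTORED:
        if u_fail < t.p_restoration_failure:
            s.restoration_failures += 1
            if s.restoration_failures >= t.restoration_failures_before_crown:
                s.health = HealthState.CROWNED
                events.append(CostEvent("crown", costs.crown, year))
            elif u_repair < t.p_repair:
                events.append(CostEvent("restoration_repair", costs.restoration_repair, year))
            else:
                events.append(
                    CostEvent("restoration_replacement", costs.restoration_replacement, year)
                )
    elif h is HealthState.CROWNED:
        if u_fail < t.p_crown_failure:
            if not s.crown_replaced:
                s.crown_replaced = True
                events.append(CostEvent("crown_replacement", costs.crown_replacement, year))
            else:
                s.health = HealthState.ROOT_FILLED
                events.append(
                    CostEvent("root_canal_treatment", costs.root_canal_treatment, year)
                )
    elif h is HealthState.ROOT_FILLED:
        if u_fail < t.p_rootfill_failure:
            s.health = HealthState.RETREATED_NONSURG
            events.append(
                CostEvent("nonsurgical_retreatment", costs.nonsurgical_retreatment, year)
            )
    elif h is HealthState.RETREATED_NONSURG:
        if u_fail < t.p_retreat_failure:
            s.health = HealthState.RETREATED_SURG
            events.append(CostEvent("surgical_retreatment", costs.surgical_retreatment, year))
    elif h is HealthState.RETREATED_SURG:
        if u_fail < t.p_surg_retreat_failure:
            s.health = HealthState.EXTRACTED_IMPLANT
            s.alive_tooth = False
            events.append(CostEvent("extraction", costs.extraction, year))
            events.append(CostEvent("implant_crown", costs.implant_crown, year))
    return events


# -- public single-step API --


def natural_step(s: ToothState, t: TransitionTable, rng: np.random.Generator) -> ToothState:
    """One annual cycle of untreated caries onset/progression.

    Returns a new ToothState; ``s`` is not modified.  Treated and
    absorbing states pass through unchanged.
    """
    bad = t.violations()
    if bad:
        raise ValueError("; ".join(bad))
    out = ToothState(**{f.name: getattr(s, f.name) for f in fields(ToothState)})
    if out.health in UNTREATED_STATES:
        _natural_core(out, t, float(rng.random()))
    return out


def treatment_step(
    s: ToothState, t: TransitionTable, costs: "CostTable", rng: np.random.Generator, year: int = 0
):
    """One annual cycle of treated-state hazards.  Returns (new state, events)."""
    bad = t.violations()
    if bad:
        raise ValueError("; ".join(bad))
    out = ToothState(**{f.name: getattr(s, f.name) for f in fields(ToothState)})
    if out.health not in TREATED_STATES:
        return out, []
    events = _treatment_core(
        out, t, costs, year, float(rng.random()), float(rng.random()), float(rng.random())
    )
    return out, events
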