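"""Model parameters, uncertainty distributions, and PSA sampling.

Every quantity a single model evaluation needs — annual transition
probabilities, diagnostic accuracy per lesion depth, per-event treatment
costs, the cohort risk profile and the discount rate — is collected in a
:class:`ParameterSet`.  Probabilistic sensitivity analysis (PSA) draws
whole parameter sets from a :class:`PSAConfig`, which marks a subset of
parameters as uncertain and assigns each a :class:`Distribution`
(point, uniform, or triangular — the shapes conventional in
health-economic PSA).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .markov import TransitionTable

LESION_DEPTHS = ("E2", "D1", "D2D3")
INITIAL_STATES = ("sound", "E2", "D1", "D2D3")
TRAINING_FRACTIONS = (0.10, 0.25, 0.50, 1.00)

ACCURACY_METRICS = ("sens_E2", "sens_D1", "sens_D2D3", "specificity")


class ParameterValidationError(ValueError):
    """A sampled or supplied parameter violates its invariants."""


@dataclass(frozen=True)
class Distribution:
    """A univariate uncertainty distribution for one scalar parameter.

    ``point`` distributions are degenerate (low == high); ``uniform`` is
    parameterized by (low, high); ``triangular`` by (low, mode, high).
    """

    kind: str
    low: float
    high: float
    mode: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("point", "uniform", "triangular"):
            raise ParameterValidationError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "point":
            if self.low != self.high:
                raise ParameterValidationError("point distribution requires low == high")
        if self.low > self.high:
            raise ParameterValidationError(f"low {self.low} > high {self.high}")
        if self.kind == "triangular":
            if self.mode is None:
                raise ParameterValidationError("triangular distribution requires a mode")
            if not (self.low <= self.mode <= self.high):
                raise ParameterValidationError(
                    f"triangular mode {self.mode} outside [{self.low}, {self.high}]"
                )

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point" or self.low == self.high:
            return float(self.low)
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(rng.triangular(self.low, self.mode, self.high))

    def mean(self) -> float:
        if self.kind == "point":
            return float(self.low)
        if self.kind == "uniform":
            return (self.low + self.high) / 2.0
        return (self.low + self.mode + self.high) / 3.0


def point(value: float) -> Distribution:
    return Distribution("point", value, value)


def uniform(low: float, high: float) -> Distribution:
    return Distribution("uniform", low, high)


def triangular(low: float, mode: float, high: float) -> Distribution:
    return Distribution("triangular", low, high, mode=mode)


def sample_distribution(d: Distribution, rng: np.random.Generator) -> float:
    """Draw one value from ``d``; always within [d.low, d.high]."""
    return d.sample(rng)


@dataclass
class AccuracyProfile:
    """Sensitivity per lesion depth (E2 / D1 / D2–D3) plus specificity."""

    sensitivity_by_depth: dict = field(default_factory=dict)
    specificity: float = 1.0

    def sensitivity(self, depth: str) -> float:
        return self.sensitivity_by_depth[depth]

    def violations(self, name: str) -> list:
        out = []
        for depth in LESION_DEPTHS:
            if depth not in self.sensitivity_by_depth:
                out.append(f"{name}: missing sensitivity for depth {depth}")
                continue
            v = self.sensitivity_by_depth[depth]
            if not (0.0 <= v <= 1.0):
                out.append(f"{name}.sensitivity[{depth}] = {v} outside [0, 1]")
        if not (0.0 <= self.specificity <= 1.0):
            out.append(f"{name}.specificity = {self.specificity} outside [0, 1]")
        return out


@dataclass
class RiskProfile:
    """Caries-risk stratum of the simulated cohort.

    ``initial_state_prevalence`` gives the distribution of tooth surfaces
    over sound / E2 / D1 / D2–D3 at the start of the horizon;
    ``progression_multiplier`` scales the annual caries onset and
    progression probabilities relative to the low-risk baseline.
    """

    label: str
    initial_state_prevalence: dict
    progression_multiplier: float = 1.0

    def violations(self) -> list:
        out = []
        if self.label not in ("low", "high"):
            out.append(f"risk.label = {self.label!r} not in {{low, high}}")
        total = 0.0
        for s in INITIAL_STATES:
            v = self.initial_state_prevalence.get(s, 0.0)
            if not (0.0 <= v <= 1.0):
                out.append(f"risk.initial_state_prevalence[{s}] = {v} outside [0, 1]")
            total += v
        if abs(total - 1.0) > 1e-9:
            out.append(f"risk.initial_state_prevalence sums to {total}, expected 1")
        if self.progression_multiplier <= 0:
            out.append(f"risk.progression_multiplier = {self.progression_multiplier} must be > 0")
        return out


@dataclass
class CostTable:
    """Per-event costs in euros (mixed public–private payer totals)."""

    radiograph_exam: float = 0.0
    visual_tactile_exam: float = 0.0
    ai_application: float = 0.0
    infiltration: float = 0.0
    composite_restoration: float = 0.0
    restoration_repair: float = 0.0
    restoration_replacement: float = 0.0
    crown: float = 0.0
    crown_replacement: float = 0.0
    root_canal_treatment: float = 0.0
    nonsurgical_retreatment: float = 0.0
    surgical_retreatment: float = 0.0
    extraction: float = 0.0
    implant_crown: float = 0.0

    def violations(self) -> list:
        return [
            f"costs.{f.name} = {getattr(self, f.name)} must be >= 0"
            for f in dataclasses.fields(self)
            if getattr(self, f.name) < 0
        ]


@dataclass
class ParameterSet:
    """All inputs for one model evaluation (one PSA draw)."""

    transitions: TransitionTable
    dentist_accuracy: AccuracyProfile
    ai_accuracy: AccuracyProfile
    visual_tactile_accuracy: AccuracyProfile
    costs: CostTable
    risk: RiskProfile
    discount_rate: float = 0.03
    ai_training_fraction: float = 1.00
    # How an unstaged false-positive radiographic call is acted upon:
    # with this probability it is treated as an advanced lesion
    # (restoration), otherwise as an initial one (infiltration).
    fp_advanced_share: float = 0.2

    def effective_transitions(self) -> TransitionTable:
        """Transition table with the risk profile's progression multiplier
        applied to caries onset and lesion progression (capped at 1)."""
        m = self.risk.progression_multiplier
        if m == 1.0:
            return self.transitions
        t = copy.copy(self.transitions)
        t.p_sound_to_E2 = min(1.0, t.p_sound_to_E2 * m)
        t.p_E2_to_D1 = min(1.0, t.p_E2_to_D1 * m)
        t.p_D1_to_D2D3 = min(1.0, t.p_D1_to_D2D3 * m)
        return t


def validate_parameter_set(p: ParameterSet) -> list:
    """Return a list of human-readable invariant violations (empty if valid)."""
    out = []
    out.extend(p.transitions.violations())
    out.extend(p.dentist_accuracy.violations("dentist_accuracy"))
    out.extend(p.ai_accuracy.violations("ai_accuracy"))
    out.extend(p.visual_tactile_accuracy.violations("visual_tactile_accuracy"))
    for depth in ("E2", "D1"):
        v = p.visual_tactile_accuracy.sensitivity_by_depth.get(depth, 0.0)
        if v != 0.0:
            out.append(
                f"visual_tactile_accuracy.sensitivity[{depth}] = {v}; initial lesions "
                "are radiograph-only, so visual-tactile sensitivity must be 0"
            )
    out.extend(p.costs.violations())
    out.extend(p.risk.violations())
    if p.discount_rate < 0:
        out.append(f"discount_rate = {p.discount_rate} must be >= 0")
    if p.ai_training_fraction not in TRAINING_FRACTIONS:
        out.append(
            f"ai_training_fraction = {p.ai_training_fraction} not in {TRAINING_FRACTIONS}"
        )
    if not (0.0 <= p.fp_advanced_share <= 1.0):
        out.append(f"fp_advanced_share = {p.fp_advanced_share} outside [0, 1]")
    return out


@dataclass
class PSAConfig:
    """Which parameters are uncertain, and with what distributions.

    ``template`` supplies the point values of every parameter; any entry
    in the distribution maps overrides the corresponding template value
    at sampling time.  The base case of the analysis marks the AI's
    accuracy (via the training-data fraction), the AI fee, the cohort
    risk profile and the transition probabilities as uncertain.
    """

    template: ParameterSet
    transition_dists: dict = field(default_factory=dict)
    ai_accuracy_dists: dict = field(default_factory=dict)  # fraction -> {metric -> Distribution}
    ai_cost_dist: Optional[Distribution] = None
    risk_profiles: dict = field(default_factory=dict)  # label -> RiskProfile
    risk_uncertain: bool = False
    training_fraction_uncertain: bool = False
    n_draws: int = 500
    seed: int = 0

    def uncertain_parameters(self) -> list:
        names = []
        if self.risk_uncertain:
            names.append("risk_profile")
        if self.training_fraction_uncertain:
            names.append("ai_training_fraction")
        if self.ai_cost_dist is not None and self.ai_cost_dist.kind != "point":
            names.append("ai_cost")
        names.extend(sorted(self.transition_dists))
        return names


def _set_accuracy(profile: AccuracyProfile, metric: str, value: float) -> None:
    if metric == "specificity":
        profile.specificity = value
    else:
        profile.sensitivity_by_depth[metric[len("sens_"):]] = value


def sample_parameter_set(cfg: PSAConfig, rng: np.random.Generator):
    """Draw one ParameterSet plus a flat record of the sampled values.

    The record (parameter label -> sampled value) is what the VOI module
    later groups on.  Out-of-bound draws are an error, never clamped.
    """
    p = copy.deepcopy(cfg.template)
    sampled: dict = {}

    if cfg.risk_uncertain:
        label = "low" if rng.random() < 0.5 else "high"
        p.risk = copy.deepcopy(cfg.risk_profiles[label])
        sampled["risk_profile"] = label

    fraction = p.ai_training_fraction
    if cfg.training_fraction_uncertain:
        fraction = TRAINING_FRACTIONS[int(rng.integers(len(TRAINING_FRACTIONS)))]
        p.ai_training_fraction = fraction
        sampled["ai_training_fraction"] = fraction

    dists = cfg.ai_accuracy_dists.get(fraction)
    if dists is not None:
        for metric in ACCURACY_METRICS:
            if metric in dists:
                _set_accuracy(p.ai_accuracy, metric, dists[metric].sample(rng))

    if cfg.ai_cost_dist is not None:
        value = cfg.ai_cost_dist.sample(rng)
        p.costs.ai_application = value
        sampled["ai_cost"] = value

    for name in sorted(cfg.transition_dists):
        value = cfg.transition_dists[name].sample(rng)
        setattr(p.transitions, name, value)
        sampled[name] = value

    violations = validate_parameter_set(p)
    if violations:
        raise ParameterValidationError("; ".join(violations))
    return p, sampled
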