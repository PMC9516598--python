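"""Synthetic, internally consistent parameter fixtures.

Rather than hard-coding the parameter estimates of any one clinical
setting, the pipeline ships a generator that reproduces the structural
features such an input set must have:

* AI accuracy follows a saturating learning curve in the training-data
  fraction (10%, 25%, 50%, 100%): the largest gain occurs between 10%
  and 25% and gains flatten afterwards, while the uncertainty band
  around each accuracy shrinks with more data.
* Two cohort risk profiles — low caries risk (mostly sound surfaces,
  baseline progression) and high risk (high lesion prevalence, faster
  progression).
* Base-case PSA distributions: uniform AI fee between 4 and 12 euros
  per application, an equiprobable low/high risk draw, a uniform draw
  over the four training fractions, and uniform/triangular bands on the
  transition probabilities.

Default magnitudes (costs from German fee-catalogue scale, annual
hazards from the restorative-dentistry literature) are fixed constants
of the generator; see docs/methods.md for the rationale per value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .markov import TransitionTable
from .parameters import (
    ACCURACY_METRICS,
    AccuracyProfile,
    CostTable,
    ParameterSet,
    PSAConfig,
    RiskProfile,
    TRAINING_FRACTIONS,
    triangular,
    uniform,
    validate_parameter_set,
)

FIXTURE_VERSION = "1"


@dataclass
class LearningCurveSpec:
    """Saturating accuracy-vs-training-data curve, one band per metric.

    mean(f)  = floor + (asymptote − floor) · (1 − exp(−rate·f))
    width(f) = width_floor + (width0 − width_floor) · exp(−rate·f)

    where f is the training fraction and width is the half-width of the
    uniform uncertainty band.  With rate ≈ 6 the 10%→25% step carries
    most of the gain, matching the qualitative behaviour of data-hungry
    image classifiers.
    """

    floors: dict = field(
        default_factory=lambda: {
            "sens_E2": 0.48,
            "sens_D1": 0.62,
            "sens_D2D3": 0.80,
            "specificity": 0.92,
        }
    )
    asymptotes: dict = field(
        default_factory=lambda: {
            "sens_E2": 0.65,
            "sens_D1": 0.82,
            "sens_D2D3": 0.95,
            "specificity": 0.975,
        }
    )
    rate: float = 6.0
    width0: float = 0.08
    width_floor: float = 0.02

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("learning-curve rate must be > 0")
        # diminishing returns: the 10%->25% step must dominate 50%->100%;
        # for the exponential form this requires a steep enough rate
        first = math.exp(-0.10 * self.rate) - math.exp(-0.25 * self.rate)
        last = math.exp(-0.50 * self.rate) - math.exp(-1.00 * self.rate)
        if first < last:
            raise ValueError(
                f"rate {self.rate} too shallow: the 10%->25% gain must exceed "
                "the 50%->100% gain"
            )

    def mean(self, metric: str, fraction: float) -> float:
        lo, hi = self.floors[metric], self.asymptotes[metric]
        return lo + (hi - lo) * (1.0 - math.exp(-self.rate * fraction))

    def width(self, fraction: float) -> float:
        return self.width_floor + (self.width0 - self.width_floor) * math.exp(
            -self.rate * fraction
        )


def accuracy_at_fraction(spec: LearningCurveSpec, fraction: float):
    """Mean AccuracyProfile and uncertainty distributions at one training
    fraction.  Returns (profile, {metric -> Distribution})."""
    if fraction not in TRAINING_FRACTIONS:
        raise ValueError(f"training fraction {fraction} not in {TRAINING_FRACTIONS}")
    w = spec.width(fraction)
    profile = AccuracyProfile(sensitivity_by_depth={}, specificity=1.0)
    dists = {}
    for metric in ACCURACY_METRICS:
        m = spec.mean(metric, fraction)
        if not (0.0 < m <= 1.0):
            raise ValueError(f"learning curve yields {metric} = {m} outside (0, 1]")
        if metric == "specificity":
            profile.specificity = m
        else:
            profile.sensitivity_by_depth[metric[len("sens_"):]] = m
        dists[metric] = uniform(max(0.0, m - w), min(1.0, m + w))
    return profile, dists


def make_risk_profiles():
    """Low- and high-risk cohorts: the high-risk profile carries more
    prevalent lesions at baseline and doubled progression hazards."""
    low = RiskProfile(
        label="low",
        initial_state_prevalence={"sound": 0.85, "E2": 0.08, "D1": 0.05, "D2D3": 0.02},
        progression_multiplier=1.0,
    )
    high = RiskProfile(
        label="high",
        initial_state_prevalence={"sound": 0.30, "E2": 0.30, "D1": 0.24, "D2D3": 0.16},
        progression_multiplier=2.2,
    )
    return low, high


def default_transition_table() -> TransitionTable:
    """Point values of the annual hazards (low-risk baseline)."""
    return TransitionTable(
        p_sound_to_E2=0.03,
        p_E2_to_D1=0.25,
        p_D1_to_D2D3=0.30,
        p_arrest_failure=0.02,
        p_restoration_failure=0.06,
        p_crown_failure=0.05,
        p_endo_complication=0.03,
        p_rootfill_failure=0.07,
        p_retreat_failure=0.12,
        p_surg_retreat_failure=0.15,
        restoration_failures_before_crown=3,
        p_repair=0.5,
    )


def default_transition_dists() -> dict:
    """PSA bands around the point hazards (uniform for the sparse-evidence
    progression rates, triangular for the better-studied failure rates)."""
    return {
        "p_sound_to_E2": uniform(0.02, 0.04),
        "p_E2_to_D1": uniform(0.20, 0.30),
        "p_D1_to_D2D3": uniform(0.25, 0.35),
        "p_arrest_failure": uniform(0.01, 0.03),
        "p_restoration_failure": triangular(0.04, 0.06, 0.08),
        "p_crown_failure": triangular(0.03, 0.05, 0.07),
        "p_endo_complication": triangular(0.02, 0.03, 0.04),
        "p_rootfill_failure": triangular(0.05, 0.07, 0.09),
        "p_retreat_failure": triangular(0.09, 0.12, 0.15),
        "p_surg_retreat_failure": triangular(0.11, 0.15, 0.19),
    }


def default_cost_table() -> CostTable:
    """Per-event totals in euros (German mixed public–private payer scale)."""
    return CostTable(
        radiograph_exam=6.0,
        visual_tactile_exam=4.0,
        ai_application=8.0,
        infiltration=90.0,
        composite_restoration=140.0,
        restoration_repair=70.0,
        restoration_replacement=140.0,
        crown=600.0,
        crown_replacement=600.0,
        root_canal_treatment=550.0,
        nonsurgical_retreatment=600.0,
        surgical_retreatment=650.0,
        extraction=100.0,
        implant_crown=2400.0,
    )


def dentist_accuracy() -> AccuracyProfile:
    """Radiographic accuracy of dentists without AI (meta-analytic scale:
    low sensitivity for initial lesions, high specificity)."""
    return AccuracyProfile(
        sensitivity_by_depth={"E2": 0.25, "D1": 0.40, "D2D3": 0.70},
        specificity=0.97,
    )


def visual_tactile_accuracy() -> AccuracyProfile:
    """Visual-tactile examination detects only advanced lesions."""
    return AccuracyProfile(
        sensitivity_by_depth={"E2": 0.0, "D1": 0.0, "D2D3": 0.30},
        specificity=1.0,
    )


@dataclass
class FixtureManifest:
    provenance: dict  # parameter group -> "published" | "synthetic"
    generator_seed: int
    version: str = FIXTURE_VERSION


@dataclass
class Fixture:
    template: ParameterSet
    psa_config: PSAConfig
    manifest: FixtureManifest


def make_fixture(
    seed: int = 0,
    n_draws: int = 500,
    curve: LearningCurveSpec | None = None,
) -> Fixture:
    """Build the base-case fixture: point template plus PSA configuration.

    The base case leaves the AI's accuracy (through an uncertain
    training fraction), the AI fee, the cohort risk profile and the
    transition probabilities uncertain; dentist and visual-tactile
    accuracy are fixed.  Deterministic given ``seed`` (recorded in the
    PSA config and manifest).
    """
    curve = curve or LearningCurveSpec()
    low, high = make_risk_profiles()
    ai_profile_full, _ = accuracy_at_fraction(curve, 1.00)
    ai_dists = {f: accuracy_at_fraction(curve, f)[1] for f in TRAINING_FRACTIONS}

    template = ParameterSet(
        transitions=default_transition_table(),
        dentist_accuracy=dentist_accuracy(),
        ai_accuracy=ai_profile_full,
        visual_tactile_accuracy=visual_tactile_accuracy(),
        costs=default_cost_table(),
        risk=low,
        discount_rate=0.03,
        ai_training_fraction=1.00,
        fp_advanced_share=0.2,
    )
    violations = validate_parameter_set(template)
    if violations:  # pragma: no cover - generator must produce valid sets
        raise AssertionError("; ".join(violations))

    psa_config = PSAConfig(
        template=template,
        transition_dists=default_transition_dists(),
        ai_accuracy_dists=ai_dists,
        ai_cost_dist=uniform(4.0, 12.0),
        risk_profiles={"low": low, "high": high},
        risk_uncertain=True,
        training_fraction_uncertain=True,
        n_draws=n_draws,
        seed=seed,
    )
    manifest = FixtureManifest(
        provenance={
            "transitions": "synthetic",
            "transition_dists": "synthetic",
            "dentist_accuracy": "synthetic",
            "ai_accuracy": "synthetic",
            "visual_tactile_accuracy": "synthetic",
            "costs": "synthetic",
            "risk_profiles": "synthetic",
            "ai_cost_dist": "synthetic",
            "discount_rate": "synthetic",
        },
        generator_seed=seed,
    )
    return Fixture(template, psa_config, manifest)
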