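"""Monte Carlo microsimulation engine.

The inner loop follows independent teeth through annual cycles over the
lifetime horizon (66 years for a cohort starting at age 12); the outer
loop repeats the cohort simulation across PSA draws of the parameter
set.  Per cycle the order of operations is fixed and documented:

    examination fees → examine → decide/treat → natural progression →
    treated-state failure hazards

Every random decision a tooth can face in a cycle has its own
pre-drawn uniform variate, so two strategies evaluated on the same
variate block experience identical chance events wherever their
parameters coincide (common random numbers), which sharpens incremental
cost/effect estimates considerably.

All randomness descends from a single root seed through
``numpy.random.SeedSequence`` spawning; rerunning with the same seed
reproduces every number bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import economics
from .diagnostics import Schedule, Strategy, _decide_core, _examine_core
from .markov import (
    HealthState,
    ToothState,
    TREATED_STATES,
    UNTREATED_STATES,
    _INITIAL_STATE_MAP,
    _natural_core,
    _treatment_core,
)
from .parameters import (
    INITIAL_STATES,
    ParameterSet,
    PSAConfig,
    sample_parameter_set,
)

# uniform-variate slots per cycle (one row of the per-tooth block)
_U_RADIO, _U_VT, _U_STAGE, _U_NATURAL, _U_ENDO, _U_FAIL, _U_REPAIR = range(7)
N_U_SLOTS = 7


@dataclass
class SimulationConfig:
    n_teeth: int = 1000
    horizon_years: int = 66
    cycle_years: int = 1
    seed: int = 0
    n_psa_draws: int = 500
    common_random_numbers: bool = True
    schedule: Schedule = field(default_factory=Schedule)


@dataclass
class StrategyResult:
    """Per-tooth outcomes of one cohort run under one parameter set."""

    retention_years: np.ndarray
    discounted_cost_euros: np.ndarray

    @property
    def mean_retention(self) -> float:
        return float(np.mean(self.retention_years))

    @property
    def mean_cost(self) -> float:
        return float(np.mean(self.discounted_cost_euros))

    def percentiles(self, q=(2.5, 97.5)) -> dict:
        return {
            "retention": [float(v) for v in np.percentile(self.retention_years, q)],
            "cost": [float(v) for v in np.percentile(self.discounted_cost_euros, q)],
        }


@dataclass
class PSAResults:
    """Per-draw mean (cost, effect) pairs per strategy, plus the sampled
    parameter values that produced each draw (needed for EVPPI)."""

    strategies: list
    costs: np.ndarray  # (n_draws, n_strategies) mean discounted cost
    effects: np.ndarray  # (n_draws, n_strategies) mean retention years
    sampled: pd.DataFrame  # one row per draw

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def strategy_index(self, label: str) -> int:
        return self.strategies.index(label)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in range(self.n_draws):
            for j, s in enumerate(self.strategies):
                rows.append(
                    {
                        "draw": d,
                        "strategy": s,
                        "mean_cost": self.costs[d, j],
                        "mean_effect": self.effects[d, j],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Mean and 2.5/97.5 percentiles of per-draw means, per strategy."""
        rows = []
        for j, s in enumerate(self.strategies):
            rows.append(
                {
                    "strategy": s,
                    "mean_cost": float(self.costs[:, j].mean()),
                    "cost_p2_5": float(np.percentile(self.costs[:, j], 2.5)),
                    "cost_p97_5": float(np.percentile(self.costs[:, j], 97.5)),
                    "mean_effect": float(self.effects[:, j].mean()),
                    "effect_p2_5": float(np.percentile(self.effects[:, j], 2.5)),
                    "effect_p97_5": float(np.percentile(self.effects[:, j], 97.5)),
                }
            )
        return pd.DataFrame(rows)


def make_strategies(p: ParameterSet) -> list:
    """The two comparators: dentist reading alone vs. dentist + AI."""
    return [
        Strategy("dentist_no_ai", p.dentist_accuracy, uses_ai_cost=False),
        Strategy("dentist_with_ai", p.ai_accuracy, uses_ai_cost=True),
    ]


def _strategy_for(p: ParameterSet, label: str) -> Strategy:
    for s in make_strategies(p):
        if s.label == label:
            return s
    raise ValueError(f"unknown strategy {label!r}")


def _simulate_tooth_u(
    strat: Strategy,
    p: ParameterSet,
    sched: Schedule,
    horizon: int,
    init_health: HealthState,
    u: np.ndarray,
    discount_factors: np.ndarray,
    collect_events: bool,
    trace: Optional[list] = None,
):
    """Simulate one tooth on a pre-drawn uniform block ``u`` of shape
    (horizon, N_U_SLOTS).  Returns (retention, discounted cost,
    undiscounted cost, events-or-None)."""
    tooth = ToothState(health=init_health)
    tt = p.effective_transitions()
    costs = p.costs
    vt_acc = p.visual_tactile_accuracy
    radio_acc = strat.radiograph_accuracy
    fp_share = p.fp_advanced_share
    events = [] if collect_events else None
    retention = 0
    disc_cost = 0.0
    raw_cost = 0.0

    for cycle in range(horizon):
        if not tooth.alive_tooth:
            break
        retention += 1
        if trace is not None:
            trace.append((cycle, tooth.health.value))
        df = discount_factors[cycle]
        radio_cycle = sched.is_radiograph_cycle(cycle)
        vt_cycle = sched.is_vt_cycle(cycle)

        # examination fees (charged while the tooth is in situ)
        if vt_cycle:
            raw_cost += costs.visual_tactile_exam
            disc_cost += costs.visual_tactile_exam * df
            if collect_events:
                events.append(("visual_tactile_exam", costs.visual_tactile_exam, cycle))
        if radio_cycle:
            raw_cost += costs.radiograph_exam
            disc_cost += costs.radiograph_exam * df
            if collect_events:
                events.append(("radiograph_exam", costs.radiograph_exam, cycle))
            if strat.uses_ai_cost:
                raw_cost += costs.ai_application
                disc_cost += costs.ai_application * df
                if collect_events:
                    events.append(("ai_application", costs.ai_application, cycle))

        row = u[cycle]

        # screening and treatment decision (untreated states only)
        if tooth.health in UNTREATED_STATES:
            outcome = _examine_core(
                tooth.health,
                radio_acc,
                vt_acc,
                radio_cycle,
                vt_cycle,
                fp_share,
                row[_U_RADIO],
                row[_U_VT],
                row[_U_STAGE],
            )
            for ev in _decide_core(tooth, outcome, costs, cycle):
                raw_cost += ev.euros
                disc_cost += ev.euros * df
                if collect_events:
                    events.append((ev.label, ev.euros, ev.year))

        # natural caries onset / progression
        if tooth.health in UNTREATED_STATES:
            _natural_core(tooth, tt, row[_U_NATURAL])

        # treated-state failure and complication hazards
        if tooth.health in TREATED_STATES:
            for ev in _treatment_core(
                tooth, tt, costs, cycle, row[_U_ENDO], row[_U_FAIL], row[_U_REPAIR]
            ):
                raw_cost += ev.euros
                disc_cost += ev.euros * df
                if collect_events:
                    events.append((ev.label, ev.euros, ev.year))

        tooth.age_years += 1

    return retention, disc_cost, raw_cost, events


def simulate_tooth(strat: Strategy, p: ParameterSet, cfg: SimulationConfig, rng: np.random.Generator):
    """Follow a single tooth over the horizon.  Returns (retention years,
    list of (label, euros, year) cost events)."""
    from .markov import initial_state

    horizon = cfg.horizon_years
    init = initial_state(p.risk, rng).health
    u = rng.random((horizon, N_U_SLOTS))
    dfs = economics.discount_factors(horizon, p.discount_rate)
    retention, _, _, events = _simulate_tooth_u(
        strat, p, cfg.schedule, horizon, init, u, dfs, collect_events=True
    )
    return retention, events


def tooth_trajectory(
    strat: Strategy, p: ParameterSet, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Tidy per-cycle trace of one tooth: cycle, state entering the cycle,
    and the cost events emitted in it (empty string when none)."""
    from .markov import initial_state

    horizon = cfg.horizon_years
    init = initial_state(p.risk, rng).health
    u = rng.random((horizon, N_U_SLOTS))
    dfs = economics.discount_factors(horizon, p.discount_rate)
    trace: list = []
    _, _, _, events = _simulate_tooth_u(
        strat, p, cfg.schedule, horizon, init, u, dfs, collect_events=True, trace=trace
    )
    by_cycle: dict = {}
    for label, euros, year in events:
        by_cycle.setdefault(year, []).append(f"{label}:{euros:g}")
    return pd.DataFrame(
        [
            {"cycle": c, "state": s, "cost_events": ";".join(by_cycle.get(c, []))}
            for c, s in trace
        ]
    )


def _draw_initial_healths(p: ParameterSet, n: int, rng: np.random.Generator):
    prev = np.array(
        [p.risk.initial_state_prevalence.get(s, 0.0) for s in INITIAL_STATES], dtype=float
    )
    idx = rng.choice(len(INITIAL_STATES), size=n, p=prev / prev.sum())
    return [_INITIAL_STATE_MAP[INITIAL_STATES[i]] for i in idx]


def _run_cohort_on(
    strat: Strategy,
    p: ParameterSet,
    sched: Schedule,
    horizon: int,
    init_healths,
    u: np.ndarray,
) -> StrategyResult:
    n = len(init_healths)
    retention = np.empty(n, dtype=float)
    cost = np.empty(n, dtype=float)
    dfs = economics.discount_factors(horizon, p.discount_rate)
    for i in range(n):
        r, c, _, _ = _simulate_tooth_u(
            strat, p, sched, horizon, init_healths[i], u[i], dfs, collect_events=False
        )
        retention[i] = r
        cost[i] = c
    return StrategyResult(retention, cost)


def run_cohort(
    strat: Strategy,
    p: ParameterSet,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> StrategyResult:
    """Simulate ``cfg.n_teeth`` independent teeth under one strategy."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    init = _draw_initial_healths(p, cfg.n_teeth, rng)
    u = rng.random((cfg.n_teeth, cfg.horizon_years, N_U_SLOTS))
    return _run_cohort_on(strat, p, cfg.schedule, cfg.horizon_years, init, u)


def run_psa(
    strategy_labels,
    psa_cfg: PSAConfig,
    sim_cfg: SimulationConfig,
) -> PSAResults:
    """Outer PSA loop: sample a ParameterSet per draw, evaluate every
    strategy on it (with common random numbers by default), and collect
    per-draw mean cost and retention."""
    labels = list(strategy_labels)
    n_draws = sim_cfg.n_psa_draws
    root = np.random.SeedSequence(sim_cfg.seed)
    children = root.spawn(n_draws)

    costs = np.empty((n_draws, len(labels)), dtype=float)
    effects = np.empty((n_draws, len(labels)), dtype=float)
    sampled_rows = []

    for d in range(n_draws):
        param_ss, sim_ss = children[d].spawn(2)
        param_rng = np.random.default_rng(param_ss)
        p, sampled = sample_parameter_set(psa_cfg, param_rng)
        sampled_rows.append(sampled)

        if sim_cfg.common_random_numbers:
            sim_rng = np.random.default_rng(sim_ss)
            init = _draw_initial_healths(p, sim_cfg.n_teeth, sim_rng)
            u = sim_rng.random((sim_cfg.n_teeth, sim_cfg.horizon_years, N_U_SLOTS))
            for j, label in enumerate(labels):
                res = _run_cohort_on(
                    _strategy_for(p, label), p, sim_cfg.schedule, sim_cfg.horizon_years, init, u
                )
                costs[d, j] = res.mean_cost
                effects[d, j] = res.mean_retention
        else:
            strat_seeds = sim_ss.spawn(len(labels))
            for j, label in enumerate(labels):
                sim_rng = np.random.default_rng(strat_seeds[j])
                init = _draw_initial_healths(p, sim_cfg.n_teeth, sim_rng)
                u = sim_rng.random((sim_cfg.n_teeth, sim_cfg.horizon_years, N_U_SLOTS))
                res = _run_cohort_on(
                    _strategy_for(p, label), p, sim_cfg.schedule, sim_cfg.horizon_years, init, u
                )
                costs[d, j] = res.mean_cost
                effects[d, j] = res.mean_retention

    sampled_df = pd.DataFrame(sampled_rows)
    sampled_df.insert(0, "draw", np.arange(n_draws))
    return PSAResults(labels, costs, effects, sampled_df)
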