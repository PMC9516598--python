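"""Microsimulation engine: closed-form traces, chain oracle, seeding."""

import copy

import numpy as np
import pytest

import cariesim as cs
from cariesim.markov import HealthState as H
from cariesim.parameters import AccuracyProfile, RiskProfile
from cariesim.simulate import run_cohort, run_psa, simulate_tooth


def zeroed(template):
    """Template with every stochastic hazard and misread switched off."""
    p = copy.deepcopy(template)
    for name in p.transitions.PROBABILITY_FIELDS:
        setattr(p.transitions, name, 0.0)
    p.transitions.p_repair = 0.5
    for prof in (p.dentist_accuracy, p.ai_accuracy, p.visual_tactile_accuracy):
        prof.specificity = 1.0
    p.risk = RiskProfile("low", {"sound": 1.0, "E2": 0.0, "D1": 0.0, "D2D3": 0.0}, 1.0)
    return p


def exam_stream(costs, horizon, rate, with_ai):
    years = np.arange(horizon)
    df = (1 + rate) ** -years.astype(float)
    total = costs.visual_tactile_exam * df.sum()
    radio = df[years % 2 == 0].sum()
    total += costs.radiograph_exam * radio
    if with_ai:
        total += costs.ai_application * radio
    return total


class TestSimulateTooth:
    def test_sound_forever_costs_only_exams(self, template):
        p = zeroed(template)
        cfg = cs.SimulationConfig(n_teeth=1, horizon_years=66)
        strat = cs.make_strategies(p)[0]
        retention, events = simulate_tooth(strat, p, cfg, np.random.default_rng(0))
        assert retention == 66
        labels = {lab for lab, _, _ in events}
        assert labels == {"visual_tactile_exam", "radiograph_exam"}
        disc = sum(eur / 1.03**yr for _, eur, yr in events)
        assert disc == pytest.approx(exam_stream(p.costs, 66, 0.03, with_ai=False))

    def test_forced_cascade_hand_trace(self, template):
        """A certain-detection, certain-failure configuration unrolls the
        whole cascade deterministically; retention and the event sequence
        are checked against a hand computation."""
        p = zeroed(template)
        p.risk = RiskProfile("high", {"sound": 0.0, "E2": 0.0, "D1": 0.0, "D2D3": 1.0}, 1.0)
        p.dentist_accuracy = AccuracyProfile({"E2": 1.0, "D1": 1.0, "D2D3": 1.0}, 1.0)
        t = p.transitions
        t.p_restoration_failure = 1.0
        t.restoration_failures_before_crown = 1
        t.p_crown_failure = 1.0
        t.p_rootfill_failure = 1.0
        t.p_retreat_failure = 1.0
        t.p_surg_retreat_failure = 1.0
        cfg = cs.SimulationConfig(n_teeth=1, horizon_years=10)
        strat = cs.make_strategies(p)[0]
        retention, events = simulate_tooth(strat, p, cfg, np.random.default_rng(0))
        assert retention == 6
        treatment_sequence = [
            (lab, yr)
            for lab, _, yr in events
            if lab not in ("visual_tactile_exam", "radiograph_exam")
        ]
        assert treatment_sequence == [
            ("composite_restoration", 0),
            ("crown", 0),
            ("crown_replacement", 1),
            ("root_canal_treatment", 2),
            ("nonsurgical_retreatment", 3),
            ("surgical_retreatment", 4),
            ("extraction", 5),
            ("implant_crown", 5),
        ]

    def test_undetectable_disease_generates_no_treatment_costs(self, template):
        p = copy.deepcopy(template)
        p.risk = RiskProfile("high", {"sound": 0.0, "E2": 0.0, "D1": 0.0, "D2D3": 1.0}, 1.0)
        for prof in (p.dentist_accuracy, p.ai_accuracy, p.visual_tactile_accuracy):
            prof.sensitivity_by_depth = {"E2": 0.0, "D1": 0.0, "D2D3": 0.0}
            prof.specificity = 1.0
        cfg = cs.SimulationConfig(n_teeth=1, horizon_years=66)
        strat = cs.make_strategies(p)[0]
        retention, events = simulate_tooth(strat, p, cfg, np.random.default_rng(1))
        assert retention == 66  # untreated lesions never enter the cascade
        assert {lab for lab, _, _ in events} == {"visual_tactile_exam", "radiograph_exam"}


class TestCollapsedChainOracle:
    def test_mean_retention_matches_exact_expectation(self, template):
        """Certain immediate restoration plus certain downstream failures
        collapse the model to restored -> (geometric endodontic hazard) ->
        three deterministic retreatment years -> extraction.  Retention is
        min(T + 4, horizon) with T geometric; the simulated cohort mean
        must sit within 3 standard errors of the exact expectation."""
        h, horizon, n = 0.10, 66, 1000
        p = zeroed(template)
        p.risk = RiskProfile("high", {"sound": 0.0, "E2": 0.0, "D1": 0.0, "D2D3": 1.0}, 1.0)
        p.dentist_accuracy = AccuracyProfile({"E2": 1.0, "D1": 1.0, "D2D3": 1.0}, 1.0)
        t = p.transitions
        t.p_endo_complication = h
        t.p_rootfill_failure = 1.0
        t.p_retreat_failure = 1.0
        t.p_surg_retreat_failure = 1.0

        # independent oracle: exact expectation by enumeration
        probs = np.array([h * (1 - h) ** t for t in range(horizon)])
        values = np.minimum(np.arange(horizon) + 4, horizon)
        expected = float((probs * values).sum() + (1 - probs.sum()) * horizon)
        variance = float((probs * values**2).sum() + (1 - probs.sum()) * horizon**2) - expected**2

        cfg = cs.SimulationConfig(n_teeth=n, horizon_years=horizon, seed=17)
        res = run_cohort(cs.make_strategies(p)[0], p, cfg)
        se = np.sqrt(variance / n)
        assert abs(res.mean_retention - expected) < 3 * se


class TestRunCohort:
    def test_retention_bounded_by_horizon_and_costs_nonnegative(self, fixture_obj):
        p = fixture_obj.template
        cfg = cs.SimulationConfig(n_teeth=300, horizon_years=66, seed=5)
        for strat in cs.make_strategies(p):
            res = run_cohort(strat, p, cfg)
            assert np.all(res.retention_years <= 66)
            assert np.all(res.retention_years >= 0)
            assert np.all(res.discounted_cost_euros >= 0)

    def test_same_seed_byte_identical(self, fixture_obj):
        p = fixture_obj.template
        cfg = cs.SimulationConfig(n_teeth=100, horizon_years=66, seed=9)
        strat = cs.make_strategies(p)[1]
        a = run_cohort(strat, p, cfg)
        b = run_cohort(strat, p, cfg)
        assert np.array_equal(a.retention_years, b.retention_years)
        assert np.array_equal(a.discounted_cost_euros, b.discounted_cost_euros)

    def test_discounting_reduces_cost(self, fixture_obj):
        p0 = copy.deepcopy(fixture_obj.template)
        p0.discount_rate = 0.0
        p3 = copy.deepcopy(fixture_obj.template)
        p3.discount_rate = 0.03
        cfg = cs.SimulationConfig(n_teeth=100, horizon_years=66, seed=4)
        r0 = run_cohort(cs.make_strategies(p0)[0], p0, cfg)
        r3 = run_cohort(cs.make_strategies(p3)[0], p3, cfg)
        assert np.all(r3.discounted_cost_euros <= r0.discounted_cost_euros)
        assert r3.mean_cost < r0.mean_cost

    def test_identical_accuracy_strategies_coincide(self, fixture_obj):
        """With equal reading accuracy and no AI fee the two arms are the
        same data-generating process; under a shared seed they coincide."""
        p = copy.deepcopy(fixture_obj.template)
        p.ai_accuracy = copy.deepcopy(p.dentist_accuracy)
        cfg = cs.SimulationConfig(n_teeth=200, horizon_years=66, seed=21)
        no_ai = cs.Strategy("dentist_no_ai", p.dentist_accuracy, uses_ai_cost=False)
        twin = cs.Strategy("dentist_with_ai", p.ai_accuracy, uses_ai_cost=False)
        a = run_cohort(no_ai, p, cfg)
        b = run_cohort(twin, p, cfg)
        assert np.array_equal(a.retention_years, b.retention_years)
        assert np.array_equal(a.discounted_cost_euros, b.discounted_cost_euros)

    def test_sound_cohort_cost_gap_is_exactly_the_ai_fee_stream(self, template):
        p = zeroed(template)
        p.ai_accuracy = copy.deepcopy(p.dentist_accuracy)
        cfg = cs.SimulationConfig(n_teeth=50, horizon_years=66, seed=2)
        res = {s.label: run_cohort(s, p, cfg) for s in cs.make_strategies(p)}
        gap = res["dentist_with_ai"].mean_cost - res["dentist_no_ai"].mean_cost
        fee_stream = exam_stream(p.costs, 66, 0.03, True) - exam_stream(p.costs, 66, 0.03, False)
        assert gap == pytest.approx(fee_stream)


class TestToothTrajectory:
    def test_trace_is_tidy_and_consistent(self, fixture_obj):
        cfg = cs.SimulationConfig(n_teeth=1, horizon_years=30)
        strat = cs.make_strategies(fixture_obj.template)[1]
        frame = cs.tooth_trajectory(
            strat, fixture_obj.template, cfg, np.random.default_rng(3)
        )
        assert list(frame.columns) == ["cycle", "state", "cost_events"]
        assert len(frame) <= 30
        assert (frame["cycle"].diff().dropna() == 1).all()
        # exam fees appear on every traced cycle while the tooth is in situ
        assert frame["cost_events"].str.contains("visual_tactile_exam").all()


class TestRunPSA:
    def test_reproducible_and_aligned(self, fixture_obj):
        cfg = cs.SimulationConfig(n_teeth=40, horizon_years=30, seed=13, n_psa_draws=5)
        labels = ("dentist_no_ai", "dentist_with_ai")
        a = run_psa(labels, fixture_obj.psa_config, cfg)
        b = run_psa(labels, fixture_obj.psa_config, cfg)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.effects, b.effects)
        assert a.sampled.equals(b.sampled)
        assert a.costs.shape == (5, 2) and a.effects.shape == (5, 2)

    def test_point_distributions_have_zero_parameter_variance(self, fixture_obj):
        cfg_psa = copy.deepcopy(fixture_obj.psa_config)
        cfg_psa.transition_dists = {}
        cfg_psa.ai_accuracy_dists = {}
        cfg_psa.ai_cost_dist = cs.point(8.0)
        cfg_psa.risk_uncertain = False
        cfg_psa.training_fraction_uncertain = False
        cfg = cs.SimulationConfig(n_teeth=30, horizon_years=20, seed=1, n_psa_draws=6)
        psa = run_psa(("dentist_no_ai", "dentist_with_ai"), cfg_psa, cfg)
        assert (psa.sampled["ai_cost"] == 8.0).all()

    def test_single_draw_point_psa_matches_cohort_statistics(self, fixture_obj):
        """A 1-draw PSA with point parameters is one cohort run; its means
        must agree with run_cohort at the same size within sampling error."""
        cfg_psa = copy.deepcopy(fixture_obj.psa_config)
        cfg_psa.transition_dists = {}
        cfg_psa.ai_accuracy_dists = {}
        cfg_psa.ai_cost_dist = cs.point(8.0)
        cfg_psa.risk_uncertain = False
        cfg_psa.training_fraction_uncertain = False
        cfg = cs.SimulationConfig(n_teeth=400, horizon_years=66, seed=8, n_psa_draws=1)
        psa = run_psa(("dentist_no_ai",), cfg_psa, cfg)
        ref = run_cohort(
            cs.make_strategies(cfg_psa.template)[0], cfg_psa.template, cfg
        )
        se = np.std(ref.retention_years) / np.sqrt(cfg.n_teeth)
        assert abs(psa.effects[0, 0] - ref.mean_retention) < 4 * se + 1e-9

    def test_common_random_numbers_reduce_incremental_variance(self, fixture_obj):
        cfg_crn = cs.SimulationConfig(n_teeth=60, horizon_years=40, seed=3, n_psa_draws=12)
        cfg_ind = copy.deepcopy(cfg_crn)
        cfg_ind.common_random_numbers = False
        labels = ("dentist_no_ai", "dentist_with_ai")
        crn = run_psa(labels, fixture_obj.psa_config, cfg_crn)
        ind = run_psa(labels, fixture_obj.psa_config, cfg_ind)
        # not a strict guarantee draw by draw, but variance of the paired
        # difference should not explode under CRN
        v_crn = np.var(crn.costs[:, 1] - crn.costs[:, 0])
        v_ind = np.var(ind.costs[:, 1] - ind.costs[:, 0])
        assert v_crn < 2.0 * v_ind
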