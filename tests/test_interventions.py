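import numpy as np
import pytest

from fapsim.cohort import Individual
from fapsim.engine import RunConfig, run_strategy
from fapsim.interventions import (
    CycleEvents,
    Strategy,
    StrategyKind,
    apply_aspirin_cycle,
    do_idp,
    do_ipaa,
    do_surveillance,
    polyp_recurrence_prob,
)
from fapsim.natural_history import Compartment, DiseaseState, PolypClass


class _ForcedRng:
    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


def _person(comp=Compartment.POLYP, polyp_class=PolypClass.HIGH_10PLUSMM, **kw):
    ind = Individual(id=0, sex=0, age=30, **kw)
    ind.disease = DiseaseState(comp, polyp_class)
    return ind


IDP_STRAT = Strategy(StrategyKind.IDP)
ASPIRIN_STRAT = Strategy(StrategyKind.IDP_ASPIRIN)


class TestDoSurveillance:
    def test_high_risk_polyp_detected_below_sensitivity(self, params):
        ind = _person()
        ev = do_surveillance(ind, params, _ForcedRng([0.5]), IDP_STRAT)  # 0.5 < 0.976
        assert ev.polyp_detected and ev.colonoscopy_done

    def test_low_risk_polyp_missed_above_sensitivity(self, params):
        ind = _person(polyp_class=PolypClass.LOW_5TO9MM)
        ev = do_surveillance(ind, params, _ForcedRng([0.90, 0.9]), IDP_STRAT)  # 0.90 > 0.865
        assert not ev.polyp_detected

    def test_polyp_free_never_triggers_detection(self, params):
        # specificity 1: only the tiny no-polypectomy perforation risk remains
        ind = _person(Compartment.POLYP_FREE)
        for draw in (0.0, 0.5, 0.999):
            ev = do_surveillance(ind, params, _ForcedRng([max(draw, 0.001)]), IDP_STRAT)
            assert not ev.polyp_detected

    def test_preclinical_screen_detection_reassigns_to_clinical(self, params):
        ind = _person(Compartment.PRECLIN_III)
        ev = do_surveillance(ind, params, _ForcedRng([0.5, 0.9]), IDP_STRAT)
        assert ev.preclinical_detected_stage == "III"
        assert ind.disease.compartment is Compartment.CLIN_III
        assert ind.disease.years_since_dx == 1

    def test_rejected_for_no_intervention_strategy(self, params, rng):
        with pytest.raises(ValueError):
            do_surveillance(_person(), params, rng, Strategy(StrategyKind.NONE))


class TestDoIdp:
    def test_removal_leaves_polyp_free(self, params, rng):
        ind = _person()
        ev = CycleEvents(colonoscopy_done=True, polyp_detected=True)
        out = do_idp(ind, ev, params, rng)
        assert ind.disease.compartment is Compartment.POLYP_FREE
        assert out.polypectomy_done

    def test_bleeding_draw_below_published_probability(self, params):
        ind = _person()
        ev = CycleEvents(colonoscopy_done=True, polyp_detected=True)
        out = do_idp(ind, ev, params, _ForcedRng([0.9, 0.01]))  # 0.01 < 0.023
        assert out.bleeding and not out.perforation

    def test_zero_complication_probabilities(self, params, rng):
        p = params.copy()
        p.adverse_events.p_idp_perforation = 0.0
        p.adverse_events.p_idp_bleeding = 0.0
        for _ in range(20):
            ev = CycleEvents(colonoscopy_done=True, polyp_detected=True)
            out = do_idp(_person(), ev, p, rng)
            assert not out.perforation and not out.bleeding

    def test_requires_detected_polyp(self, params, rng):
        with pytest.raises(ValueError):
            do_idp(_person(), CycleEvents(colonoscopy_done=True), params, rng)


class TestPolypRecurrenceProb:
    def test_probability_scale_product_with_aspirin(self, params):
        ind = _person(Compartment.POLYP_FREE)
        assert polyp_recurrence_prob(ind, params, aspirin_taken=True) == pytest.approx(
            0.554 * 0.37
        )

    def test_non_adherent_year_uses_base_probability(self, params):
        ind = _person(Compartment.POLYP_FREE)
        assert polyp_recurrence_prob(ind, params, aspirin_taken=False) == 0.554

    def test_rr_one_neutralises_aspirin(self, params):
        p = params.copy()
        p.effectiveness.rr_polyp_with_aspirin = 1.0
        ind = _person(Compartment.POLYP_FREE)
        assert polyp_recurrence_prob(ind, p, aspirin_taken=True) == pytest.approx(0.554)

    def test_rate_scale_alternative(self, params):
        p = params.copy()
        p.effectiveness.rr_on_probability_scale = False
        ind = _person(Compartment.POLYP_FREE)
        expected = 1.0 - (1.0 - 0.554) ** 0.37
        assert polyp_recurrence_prob(ind, p, aspirin_taken=True) == pytest.approx(expected)

    def test_post_ipaa_destined_uniform_timing_hazard(self, params):
        ind = _person(Compartment.POLYP_FREE, had_ipaa=True)
        ind.ipaa_polyp_destiny = "will_recur"
        assert polyp_recurrence_prob(ind, params, remaining_horizon_years=20) == 0.05
        ind.ipaa_polyp_destiny = "never"
        assert polyp_recurrence_prob(ind, params, remaining_horizon_years=20) == 0.0

    def test_rejected_outside_polyp_free(self, params):
        with pytest.raises(ValueError):
            polyp_recurrence_prob(_person(Compartment.POLYP), params)


class TestApplyAspirinCycle:
    def test_perfect_adherence_takes_every_cycle(self, params, rng):
        ind = _person(Compartment.POLYP_FREE, on_aspirin=True)
        for _ in range(10):
            assert apply_aspirin_cycle(ind, params, rng).aspirin_taken

    def test_certain_serious_bleed_halts_permanently(self, params, rng):
        p = params.copy()
        p.adverse_events.p_aspirin_serious_bleed = 1.0
        ind = _person(Compartment.POLYP_FREE, on_aspirin=True)
        ev = apply_aspirin_cycle(ind, p, rng)
        assert ev.aspirin_taken and ev.aspirin_gi_event
        assert not ind.on_aspirin
        assert not apply_aspirin_cycle(ind, p, rng).aspirin_taken

    def test_partial_adherence_long_run_fraction(self, params):
        p = params.copy()
        p.economics.adherence_aspirin = 0.8
        rng = np.random.default_rng(99)
        ind = _person(Compartment.POLYP_FREE, on_aspirin=True)
        n = 100_000
        taken = sum(
            apply_aspirin_cycle(ind, p, rng, first_year=False).aspirin_taken
            for _ in range(n)
        )
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(taken / n - 0.8) < 2 * se + 1e-9


class TestDoIpaa:
    def test_destiny_fraction_matches_lifetime_probability(self, params):
        rng = np.random.default_rng(5)
        n = 100_000
        recur = 0
        for _ in range(n):
            ind = _person()
            do_ipaa(ind, params, rng)
            recur += ind.ipaa_polyp_destiny == "will_recur"
        se = np.sqrt(0.036 * 0.964 / n)
        assert abs(recur / n - 0.036) < 2 * se

    def test_never_destiny_stays_polyp_free(self, params, rng):
        ind = _person()
        do_ipaa(ind, params, _ForcedRng([0.99]))
        assert ind.ipaa_polyp_destiny == "never"
        assert ind.disease.compartment is Compartment.POLYP_FREE

    def test_occult_cancer_diagnosed_at_pathology(self, params, rng):
        ind = _person(Compartment.PRECLIN_II)
        ev = do_ipaa(ind, params, rng)
        assert ev.ipaa_done
        assert ind.disease.compartment is Compartment.CLIN_II
        assert ind.disease.years_since_dx == 1

    def test_second_surgery_rejected(self, params, rng):
        ind = _person()
        do_ipaa(ind, params, rng)
        with pytest.raises(ValueError):
            do_ipaa(ind, params, rng)


class TestStrategyLevelInvariants:
    def test_no_intervention_never_accrues_procedure_costs(
        self, zero_disease_params, life_table, perfect_survival_table
    ):
        # with no disease and no procedures the arm costs exactly nothing
        cfg = RunConfig(n=2000, horizon=40, seed=8, strategy=Strategy(StrategyKind.NONE))
        res = run_strategy(cfg, zero_disease_params, life_table, perfect_survival_table)
        assert res.mean_cost == 0.0

    def test_perfect_sensitivity_zero_recurrence_blocks_cancer(
        self, params, life_table, survival_table
    ):
        p = params.copy()
        p.tests.sens_low_risk_polyp = 1.0
        p.tests.sens_high_risk_polyp = 1.0
        p.tests.sens_preclinical_crc = 1.0
        p.effectiveness.p_polyp_recur_after_idp = 0.0
        for k in p.natural_history.p_preclin_at_entry:
            p.natural_history.p_preclin_at_entry[k] = 0.0
        cfg = RunConfig(n=5000, horizon=40, seed=21, strategy=Strategy(StrategyKind.IDP))
        res = run_strategy(cfg, p, life_table, survival_table)
        # after the first surveillance cycle clears the baseline burden there
        # is nothing left to transform: the only cancers can arise in the
        # pre-surveillance entry cycle itself
        assert res.crc_deaths_per_1000 < 2.0

    def test_aspirin_reduces_recurrence_under_common_random_numbers(
        self, params, life_table, survival_table
    ):
        base_cfg = dict(n=20_000, horizon=40, seed=13)
        idp = run_strategy(
            RunConfig(strategy=Strategy(StrategyKind.IDP), **base_cfg),
            params, life_table, survival_table,
        )
        asp = run_strategy(
            RunConfig(strategy=Strategy(StrategyKind.IDP_ASPIRIN), **base_cfg),
            params, life_table, survival_table,
        )
        # coupled draws: the aspirin arm can only remove recurrences
        assert asp.crc_deaths_per_1000 <= idp.crc_deaths_per_1000
        assert asp.mean_cost < idp.mean_cost
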