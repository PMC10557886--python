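import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from fapsim import natural_history as nh
from fapsim.engine import RunConfig, run_strategy
from fapsim.interventions import Strategy, StrategyKind
from fapsim.natural_history import (
    CLINICAL,
    Compartment,
    DiseaseState,
    advance_disease,
    calibrate_multiplier,
    cohort_oracle,
    crc_death_prob,
    lifetime_crc_death_probability,
    polyp_to_preclinical_prob,
)
from fapsim.synthetic_data import make_calibration_targets


class _ForcedRng:
    """Feeds a fixed sequence of 'uniform' draws."""

    def __init__(self, values):
        self.values = list(values)

    def random(self):
        return self.values.pop(0)


class TestPolypToPreclinicalProb:
    def test_age_band_values(self, params):
        assert polyp_to_preclinical_prob(25, params) == 0.015982
        assert polyp_to_preclinical_prob(30, params) == 0.113758
        assert polyp_to_preclinical_prob(29, params) == 0.015982  # "<30" band edge

    def test_negative_age_rejected(self, params):
        with pytest.raises(ValueError):
            polyp_to_preclinical_prob(-2, params)


class TestAdvanceDisease:
    def test_preclin_iv_detection_draw_below_published_probability(self, params):
        state = DiseaseState(Compartment.PRECLIN_IV)
        out = advance_disease(state, 40, params, _ForcedRng([0.5]))  # 0.5 < 0.87577
        assert out.compartment is Compartment.CLIN_IV
        assert out.years_since_dx == 1

    def test_polyp_survives_draw_above_band_probability(self, params):
        state = DiseaseState(Compartment.POLYP)
        out = advance_disease(state, 40, params, _ForcedRng([0.2]))  # 0.2 > 0.113758
        assert out.compartment is Compartment.POLYP

    def test_detection_checked_before_progression(self, params):
        state = DiseaseState(Compartment.PRECLIN_I)
        # first draw (detection) misses, second (progression) hits
        out = advance_disease(state, 40, params, _ForcedRng([0.99, 0.1]))
        assert out.compartment is Compartment.PRECLIN_II

    def test_all_zero_probabilities_freeze_state(self, zero_disease_params, rng):
        p = zero_disease_params.copy()
        for k in p.natural_history.p_preclin_progress:
            p.natural_history.p_preclin_progress[k] = 0.0
        for k in p.natural_history.p_clinical_detect:
            p.natural_history.p_clinical_detect[k] = 0.0
        for comp in (Compartment.POLYP, Compartment.PRECLIN_II, Compartment.PRECLIN_IV):
            state = DiseaseState(comp)
            for _ in range(5):
                assert advance_disease(state, 45, p, rng).compartment is comp

    def test_clinical_state_ages(self, params, rng):
        state = DiseaseState(Compartment.CLIN_II, years_since_dx=4)
        out = advance_disease(state, 50, params, rng)
        assert out.compartment is Compartment.CLIN_II
        assert out.years_since_dx == 5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        comp=hs.sampled_from(list(Compartment)),
        seed=hs.integers(min_value=0, max_value=2**31 - 1),
        age=hs.integers(min_value=0, max_value=99),
    )
    def test_no_forbidden_transitions(self, comp, seed, age, params):
        ysd = 1 if comp in CLINICAL else None
        state = DiseaseState(comp, years_since_dx=ysd)
        out = advance_disease(state, age, params, np.random.default_rng(seed))
        # clinical states never revert; stages never skip or regress
        if comp in CLINICAL:
            assert out.compartment is comp
        elif comp is Compartment.POLYP:
            assert out.compartment in (Compartment.POLYP, Compartment.PRECLIN_I)
        elif comp is Compartment.POLYP_FREE:
            assert out.compartment is Compartment.POLYP_FREE
        else:
            s = state.stage_index
            allowed = {comp, Compartment(int(Compartment.CLIN_I) + s)}
            if s < 3:
                allowed.add(Compartment(int(comp) + 1))
            assert out.compartment in allowed


class TestCrcDeathProb:
    def test_complement_of_conditional_survival(self, survival_table):
        state = DiseaseState(Compartment.CLIN_III, years_since_dx=2)
        expected = 1.0 - survival_table.lookup(2, 1, 2)
        assert crc_death_prob(state, 1, survival_table) == pytest.approx(expected)

    def test_perfect_survival_entry_gives_zero(self, perfect_survival_table):
        state = DiseaseState(Compartment.CLIN_I, years_since_dx=1)
        assert crc_death_prob(state, 0, perfect_survival_table) == 0.0

    def test_cure_beyond_year_ten(self, survival_table):
        state = DiseaseState(Compartment.CLIN_IV, years_since_dx=12)
        assert crc_death_prob(state, 0, survival_table) == 0.0

    def test_non_clinical_state_rejected(self, survival_table):
        with pytest.raises(ValueError):
            crc_death_prob(DiseaseState(Compartment.PRECLIN_II), 0, survival_table)


class TestCohortOracle:
    def test_occupancy_conserved_every_cycle(self, params, life_table, survival_table):
        res = cohort_oracle(params, life_table, survival_table, 16, 40)
        assert np.all(np.abs(res.occupancy_sums() - 1.0) < 1e-12)

    def test_zero_probabilities_freeze_occupancy(
        self, zero_disease_params, zero_mortality_life_table, survival_table
    ):
        res = cohort_oracle(
            zero_disease_params, zero_mortality_life_table, survival_table, 16, 30
        )
        for occ in res.occupancy:
            assert occ["POLYP"] == pytest.approx(1.0)

    def test_microsimulation_agrees_with_oracle_within_3_se(
        self, params, life_table, survival_table
    ):
        n = 50_000
        oracle = cohort_oracle(params, life_table, survival_table, 16, 40)
        cfg = RunConfig(n=n, horizon=40, seed=17, strategy=Strategy(StrategyKind.NONE))
        micro = run_strategy(cfg, params, life_table, survival_table)
        p = oracle.crc_death_fraction
        se = np.sqrt(p * (1 - p) / n)
        assert abs(micro.crc_deaths_per_1000 / 1000 - p) < 3 * se
        # discounted QALYs converge to the oracle expectation as well
        assert abs(micro.mean_qaly - oracle.mean_discounted_qaly) < 0.05

    @pytest.mark.parametrize("seed", [101, 202, 303, 404, 505])
    def test_oracle_agreement_across_random_parameter_sets(
        self, seed, params, life_table, survival_table
    ):
        rng = np.random.default_rng(seed)
        p = params.copy()
        p.natural_history.p_polyp_to_preclin_old = rng.uniform(0.02, 0.3)
        p.natural_history.p_polyp_to_preclin_young = rng.uniform(0.001, 0.05)
        for k in p.natural_history.p_preclin_progress:
            p.natural_history.p_preclin_progress[k] = rng.uniform(0.05, 0.5)
        for k in p.natural_history.p_clinical_detect:
            p.natural_history.p_clinical_detect[k] = rng.uniform(0.05, 0.9)
        n = 20_000
        oracle = cohort_oracle(p, life_table, survival_table, 16, 40)
        cfg = RunConfig(n=n, horizon=40, seed=seed, strategy=Strategy(StrategyKind.NONE))
        micro = run_strategy(cfg, p, life_table, survival_table)
        frac = oracle.crc_death_fraction
        se = max(np.sqrt(frac * (1 - frac) / n), 1e-6)
        assert abs(micro.crc_deaths_per_1000 / 1000 - frac) < 3 * se

    def test_cumulative_incidence_monotone_in_multiplier(
        self, params, life_table, survival_table
    ):
        finals = [
            cohort_oracle(params, life_table, survival_table, 16, 40, multiplier=m)
            .cum_clinical[-1]
            for m in (0.2, 0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(finals) > 0)


class TestCalibrateMultiplier:
    def test_recovers_known_multiplier_within_5_percent(
        self, params, life_table, survival_table
    ):
        targets = make_calibration_targets(params, 1.3, (30, 40, 50, 60, 70, 80),
                                           life_table, survival_table)
        res = calibrate_multiplier(targets, params, life_table, survival_table)
        assert abs(res.multiplier - 1.3) / 1.3 < 0.05

    def test_identity_targets_give_tiny_sse(self, params, life_table, survival_table):
        targets = make_calibration_targets(params, 1.0, (30, 50, 70), life_table, survival_table)
        res = calibrate_multiplier(targets, params, life_table, survival_table)
        assert res.sse < 1e-10
        assert res.chi_square < 1e-8

    def test_zero_targets_drive_multiplier_to_lower_bound(
        self, zero_disease_params, life_table, survival_table
    ):
        from fapsim.synthetic_data import CalibrationTargets

        p = zero_disease_params.copy()
        p.natural_history.p_polyp_to_preclin_young = 0.015982
        p.natural_history.p_polyp_to_preclin_old = 0.113758
        targets = CalibrationTargets(age_upper=[40, 60], cum_incidence=[0.0, 0.0])
        res = calibrate_multiplier(targets, p, life_table, survival_table,
                                   bounds=(1e-3, 4.0))
        assert res.multiplier < 2e-3

    def test_empty_targets_rejected(self, params):
        from fapsim.synthetic_data import CalibrationTargets

        with pytest.raises(ValueError):
            calibrate_multiplier(CalibrationTargets([], []), params)


class TestLifetimeCrcDeath:
    def test_zero_natural_history_gives_zero(self, zero_disease_params, life_table, survival_table):
        assert lifetime_crc_death_probability(
            zero_disease_params, life_table, survival_table
        ) == 0.0

    def test_perfect_survival_gives_zero_even_with_cancer(
        self, params, life_table, perfect_survival_table
    ):
        assert lifetime_crc_death_probability(
            params, life_table, perfect_survival_table
        ) == pytest.approx(0.0, abs=1e-12)

    def test_oracle_and_microsim_modes_agree(self, params, life_table, survival_table):
        exact = lifetime_crc_death_probability(params, life_table, survival_table)
        n = 50_000
        micro = lifetime_crc_death_probability(
            params, life_table, survival_table, mode="microsim", n=n, seed=23
        )
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(micro - exact) < 3 * se
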