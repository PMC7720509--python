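import copy
import dataclasses

import numpy as np
import pytest

from cim.engine import (
    CANCER, CHD1, CHD2, DEAD, STATES, STR1, STRATA, T2D, WELL,
    ModelConfig,
    build_transition_matrix,
    micro_simulate,
    mix_for_share,
    run_cohort,
)
from cim.parameters import derive_activity_mix


def zeroed_band(band, **overrides):
    fields = dict(inc_t2d=0.0, inc_cancer=0.0, inc_stroke=0.0, inc_chd=0.0,
                  mort_cvd=0.0, mort_allcause=0.0, cfr_chd=0.0,
                  cfr_stroke=0.0)
    fields.update(overrides)
    return dataclasses.replace(band, **fields)


class TestTransitionMatrix:
    def test_rows_stochastic_all_bands_and_strata(self, params):
        for band in params.age_rates:
            for stratum in STRATA:
                P = build_transition_matrix(band, stratum,
                                            params.relative_risks,
                                            params.pafs)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
                assert (P >= 0).all()

    def test_well_row_with_zero_incidence(self, params):
        band = zeroed_band(params.age_rates.bands[0], mort_cvd=0.00002,
                           mort_allcause=0.00046)
        P = build_transition_matrix(band, "inactive", params.relative_risks,
                                    params.pafs)
        assert P[WELL, WELL] == pytest.approx(1 - 0.00044)
        assert P[WELL, DEAD] == pytest.approx(0.00044)

    def test_dead_is_absorbing(self, params):
        P = build_transition_matrix(params.age_rates.bands[4], "active",
                                    params.relative_risks, params.pafs)
        expected = np.zeros(8)
        expected[DEAD] = 1.0
        assert np.array_equal(P[DEAD], expected)

    def test_certain_case_fatality_blocks_first_event_state(self, params):
        band = dataclasses.replace(params.age_rates.bands[0], cfr_chd=1.0)
        P = build_transition_matrix(band, "inactive", params.relative_risks,
                                    params.pafs)
        assert P[WELL, CHD1] == 0.0
        assert P[WELL, DEAD] > band.other_cause_mortality

    def test_active_stratum_has_lower_incidence(self, params):
        band = params.age_rates.bands[4]
        Pa = build_transition_matrix(band, "active", params.relative_risks,
                                     params.pafs)
        Pi = build_transition_matrix(band, "inactive", params.relative_risks,
                                     params.pafs)
        for col in (CHD1, STR1, T2D, CANCER):
            assert Pa[WELL, col] < Pi[WELL, col]
        # state mortality is activity-independent
        assert Pa[CHD2, DEAD] == Pi[CHD2, DEAD]

    def test_cyclist_and_active_share_risk_profile(self, params):
        band = params.age_rates.bands[2]
        Pc = build_transition_matrix(band, "cyclist", params.relative_risks,
                                     params.pafs)
        Pa = build_transition_matrix(band, "active", params.relative_risks,
                                     params.pafs)
        assert np.array_equal(Pc, Pa)


class TestCohortConservation:
    def test_zero_rates_zero_discount_qaly_equals_horizon(self,
                                                          zero_risk_params):
        cfg = ModelConfig(discount_rate=0.0)
        mix = derive_activity_mix(0.06)
        trace = run_cohort(cfg, mix, zero_risk_params)
        assert trace.total_qaly == pytest.approx(25.0, abs=1e-12)

    def test_zero_rates_discounted_qaly_is_annuity_due(self,
                                                       zero_risk_params):
        cfg = ModelConfig(discount_rate=0.04)
        trace = run_cohort(cfg, derive_activity_mix(0.06), zero_risk_params)
        expected = sum(1.04 ** -t for t in range(25))
        assert trace.total_qaly == pytest.approx(expected, abs=1e-12)
        assert round(trace.total_qaly, 4) == 16.2470

    def test_rows_sum_to_one_and_dead_monotone(self, params, config):
        trace = run_cohort(config, derive_activity_mix(0.06), params)
        occ = trace.occupancy.to_numpy()
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        dead = trace.occupancy.loc[:, (slice(None), "dead")].sum(axis=1)
        assert (np.diff(dead) >= -1e-15).all()
        well = trace.occupancy.loc[:, (slice(None), "well")].sum(axis=1)
        assert (np.diff(well) <= 1e-15).all()

    def test_zero_discount_dominates_discounted(self, params, config):
        mix = derive_activity_mix(0.06)
        disc = run_cohort(config, mix, params)
        undisc = run_cohort(dataclasses.replace(config, discount_rate=0.0),
                            mix, params)
        assert undisc.total_qaly > disc.total_qaly
        assert undisc.total_cost > disc.total_cost

    def test_qaly_bounded_by_horizon_and_wellbeing(self, params, config):
        trace = run_cohort(config, derive_activity_mix(0.5), params)
        bound = config.horizon * (1 + params.costs.wellbeing_gain_active)
        assert trace.total_qaly <= bound

    def test_intervention_gains_qalys(self, params, config):
        sq = run_cohort(config, mix_for_share(config, 0.06), params)
        it = run_cohort(config, mix_for_share(config, 0.09), params,
                        intervention=True)
        assert it.total_qaly > sq.total_qaly

    def test_intervention_costs_added(self, params, config):
        mix = mix_for_share(config, 0.09)
        base = run_cohort(config, mix, params)
        arm = run_cohort(config, mix, params, intervention=True)
        invest = params.costs.invest_per_capita * config.network_km_built
        maint = (params.costs.maint_per_capita * config.network_km_built
                 * config.discount_factors.sum())
        assert arm.total_cost - base.total_cost == pytest.approx(
            invest + maint, rel=1e-12)


class TestEngineOptions:
    def test_half_cycle_correction_lowers_rewards(self, params, config):
        mix = derive_activity_mix(0.06)
        plain = run_cohort(config, mix, params)
        hcc = run_cohort(dataclasses.replace(config,
                                             half_cycle_correction=True),
                         mix, params)
        # occupancy of reward-bearing states declines, so averaging
        # start/end of cycle can only reduce the QALY total
        assert hcc.total_qaly < plain.total_qaly

    def test_wellbeing_scope_alive_adds_qalys(self, params, config):
        mix = derive_activity_mix(0.09)
        well_only = run_cohort(config, mix, params)
        alive = run_cohort(dataclasses.replace(config,
                                               wellbeing_scope="alive"),
                           mix, params)
        assert alive.total_qaly > well_only.total_qaly

    def test_t2d_mortality_decline_helps_active(self, params, config):
        mix = derive_activity_mix(1.0)  # all active
        base = run_cohort(config, mix, params)
        decl = run_cohort(dataclasses.replace(
            config, t2d_mortality_decline_active=0.9), mix, params)
        assert decl.total_qaly > base.total_qaly

    def test_horizon_below_one_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(horizon=0)


class TestMicroSimulation:
    def test_matches_cohort_within_binomial_error(self, params, config):
        n = 20_000
        mix = mix_for_share(config, 0.06)
        trace = run_cohort(config, mix, params)
        sim = micro_simulate(config, mix, params, n, seed=11)
        occ_c = trace.occupancy.to_numpy()
        occ_m = sim.occupancy.to_numpy()
        se = np.sqrt(np.maximum(occ_c * (1 - occ_c), 0.0) / n)
        # 3/n continuity allowance: cells with expected counts below a few
        # individuals have Poisson tails wider than the normal approximation
        assert (np.abs(occ_m - occ_c) <= 3 * se + 3.0 / n).all()

    def test_single_individual_walks_legal_path(self, params, config):
        mix = derive_activity_mix(0.0)
        sim = micro_simulate(config, mix, params, 1, seed=3, keep_paths=True)
        path = sim.state_paths[:, 0]
        allowed = {
            WELL: {WELL, CHD1, STR1, T2D, CANCER, DEAD},
            CHD1: {CHD2, DEAD}, CHD2: {CHD2, DEAD},
            STR1: {4, DEAD}, 4: {4, DEAD},
            T2D: {T2D, DEAD}, CANCER: {CANCER, DEAD}, DEAD: {DEAD},
        }
        for a, b in zip(path, path[1:]):
            assert b in allowed[int(a)]

    def test_zero_risk_cohort_stays_well(self, zero_risk_params, config):
        sim = micro_simulate(config, derive_activity_mix(0.5),
                             zero_risk_params, 500, seed=5)
        well = sim.occupancy.loc[:, (slice(None), "well")].sum(axis=1)
        assert (well == 1.0).all()

    def test_seed_reproducibility(self, params, config):
        mix = derive_activity_mix(0.06)
        a = micro_simulate(config, mix, params, 1000, seed=42)
        b = micro_simulate(config, mix, params, 1000, seed=42)
        assert a.total_qaly == b.total_qaly
        assert a.occupancy.equals(b.occupancy)
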