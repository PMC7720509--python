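import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cim.parameters import (
    DISEASES,
    AgeBandRates,
    ParameterValidationError,
    derive_activity_mix,
    incidence_by_activity,
    mixture_consistency_gap,
    mortality_in_state,
)


class TestPackagedTables:
    def test_printed_values_load(self, params):
        b0 = params.age_rates.bands[0]
        assert b0.age_band == "30-34"
        assert b0.inc_t2d == 0.0016
        assert b0.mort_cvd == 0.00002
        assert b0.mort_allcause == 0.00046
        assert b0.cfr_stroke == 0.2346
        rr = params.relative_risks.disease_active["t2d"]
        assert (rr.base, rr.lower, rr.upper) == (0.74, 0.72, 0.77)
        assert params.relative_risks.mortality["cancer"].base == 4.20
        assert params.relative_risks.mortality_reference["cancer"] == "all_cause"
        assert params.relative_risks.mortality_reference["chd"] == "cvd"
        assert params.costs.cost_chd_first == 22133
        assert params.costs.util_healthy == 1.0
        assert params.costs.wellbeing_gain_active == 0.05
        assert params.pafs["t2d"] == 0.07

    def test_all_nine_bands_present(self, params):
        assert len(params.age_rates) == 9
        assert params.age_rates.bands[-1].age_band == "70+"

    def test_uncertainty_families(self, params):
        assert params.costs.uncertainty["cost_t2d"] == (1968, "gamma")
        assert params.costs.uncertainty["util_t2d"] == (0.19, "beta")
        assert "invest_total" not in params.costs.uncertainty

    def test_cvd_mortality_below_all_cause_everywhere(self, params):
        for b in params.age_rates:
            assert b.mort_cvd <= b.mort_allcause


class TestValidation:
    def test_probability_out_of_range_names_cell(self):
        with pytest.raises(ParameterValidationError, match="inc_chd"):
            AgeBandRates(age_band="30-34", inc_t2d=0, inc_cancer=0,
                         inc_stroke=0, inc_chd=1.5, mort_cvd=0,
                         mort_allcause=0, cfr_chd=0, cfr_stroke=0)

    def test_cvd_exceeding_all_cause_rejected(self):
        with pytest.raises(ParameterValidationError, match="mort_cvd"):
            AgeBandRates(age_band="30-34", inc_t2d=0, inc_cancer=0,
                         inc_stroke=0, inc_chd=0, mort_cvd=0.5,
                         mort_allcause=0.1, cfr_chd=0, cfr_stroke=0)

    def test_ci_ordering_rejected(self):
        from cim.parameters import RelativeRisk
        with pytest.raises(ParameterValidationError, match="bracket"):
            RelativeRisk(base=0.74, lower=0.80, upper=0.77)


class TestActivityMix:
    @pytest.mark.parametrize("share, expected", [
        (0.06, 0.06 + 0.94 * 0.286),   # 0.32884, status quo
        (0.09, 0.09 + 0.91 * 0.286),   # 0.35026, base-case intervention
        (1.0, 1.0),
    ])
    def test_p_active(self, share, expected):
        mix = derive_activity_mix(share)
        assert mix.p_active == pytest.approx(expected, abs=1e-12)
        assert mix.p_active + mix.p_inactive == pytest.approx(1.0)

    def test_stratum_weights_sum_to_one(self):
        w = derive_activity_mix(0.09).stratum_weights
        assert sum(w.values()) == pytest.approx(1.0)
        assert w["cyclist"] == 0.09

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterValidationError):
            derive_activity_mix(1.2)


class TestIncidenceByActivity:
    def test_t2d_example(self):
        inc_a, inc_i = incidence_by_activity(0.0016, 0.07, 0.74)
        assert inc_a == pytest.approx(0.001488)
        assert inc_i == pytest.approx(0.001488 / 0.74)

    def test_no_paf_no_protection_is_identity(self):
        assert incidence_by_activity(0.01, 0.0, 1.0) == (0.01, 0.01)

    def test_zero_incidence(self):
        assert incidence_by_activity(0.0, 0.1, 0.7) == (0.0, 0.0)

    def test_clip_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            _, inc_i = incidence_by_activity(0.9, 0.0, 0.5)
        assert inc_i == 1.0

    @settings(max_examples=50, deadline=None)
    @given(inc=st.floats(0.0001, 0.05), paf=st.floats(0, 0.5),
           rr1=st.floats(0.3, 0.99), rr2=st.floats(0.3, 0.99))
    def test_inactive_incidence_decreasing_in_rr(self, inc, paf, rr1, rr2):
        lo, hi = sorted([rr1, rr2])
        _, inc_i_lo = incidence_by_activity(inc, paf, lo)
        _, inc_i_hi = incidence_by_activity(inc, paf, hi)
        assert inc_i_lo >= inc_i_hi

    @settings(max_examples=50, deadline=None)
    @given(inc=st.floats(0.0001, 0.02), paf=st.floats(0, 0.5),
           rr=st.floats(0.3, 1.0), scale=st.floats(0.1, 10.0))
    def test_both_outputs_linear_in_population_incidence(self, inc, paf, rr,
                                                         scale):
        if inc * scale > 0.5:
            return
        a1, i1 = incidence_by_activity(inc, paf, rr)
        a2, i2 = incidence_by_activity(inc * scale, paf, rr)
        assert a2 == pytest.approx(a1 * scale, rel=1e-9)
        assert i2 == pytest.approx(i1 * scale, rel=1e-9)

    def test_mixture_gap_vanishes_for_consistent_paf(self):
        # paf = p_i (1-rr) / (rr + p_i (1-rr)) makes the split reproduce
        # the population incidence exactly
        rr, p_i = 0.74, 0.6
        paf = p_i * (1 - rr) / (rr + p_i * (1 - rr))
        assert mixture_consistency_gap(0.01, paf, rr, p_i) == pytest.approx(
            0.0, abs=1e-15)
        # the printed PAFs are not exactly consistent: gap is nonzero
        assert mixture_consistency_gap(0.0016, 0.07, 0.74, 0.671) != 0.0


class TestMortalityInState:
    def test_post_chd_example(self, params):
        band = params.age_rates.bands[0]
        p = mortality_in_state(band, "post-CHD", params.relative_risks)
        assert p == pytest.approx(3.89 * 0.00002 + (0.00046 - 0.00002))

    def test_cancer_uses_all_cause(self, params):
        band = params.age_rates.bands[0]
        p = mortality_in_state(band, "cancer", params.relative_risks)
        assert p == pytest.approx(4.20 * 0.00046)

    def test_rr_one_recovers_background(self, params):
        import copy
        from cim.parameters import RelativeRisk
        rrs = copy.deepcopy(params.relative_risks)
        rrs.mortality["t2d"] = RelativeRisk(base=1.0, lower=1.0, upper=1.0)
        band = params.age_rates.bands[3]
        assert mortality_in_state(band, "t2d", rrs) == pytest.approx(
            band.mort_allcause)

    def test_unknown_disease_rejected(self, params):
        with pytest.raises(ParameterValidationError, match="unknown"):
            mortality_in_state(params.age_rates.bands[0], "gout",
                               params.relative_risks)

    def test_never_below_other_cause_mortality(self, params):
        for band in params.age_rates:
            for d in DISEASES:
                p = mortality_in_state(band, d, params.relative_risks)
                assert p >= band.other_cause_mortality - 1e-15


class TestBandLookup:
    @pytest.mark.parametrize("age, idx", [
        (30, 0), (34, 0), (35, 1), (54, 4), (69, 7), (70, 8), (95, 8),
        (29, 0),
    ])
    def test_age_to_band(self, params, age, idx):
        assert params.age_rates.band_index_for_age(age) == idx
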