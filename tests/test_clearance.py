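import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gestpbpk.clearance import (
    RowlandMartinInputs,
    apply_static_inhibition,
    clearance_breakdown,
    renal_clearance,
    rowland_matin_aucr,
    solve_fm_from_aucr,
)
from gestpbpk.engine import DosingRegimen, build_model, simulate


class TestRowlandMartin:
    def test_no_inhibition_gives_unity(self):
        for fm in (0.0, 0.3, 0.9):
            x = RowlandMartinInputs(fm_total=fm, fm_cyp1a2=1.0,
                                    inhibition_ratio=0.0)
            assert rowland_matin_aucr(x) == pytest.approx(1.0)

    def test_complete_inhibition_limit(self):
        x = RowlandMartinInputs(fm_total=1.0, fm_cyp1a2=0.5,
                                inhibition_ratio=math.inf)
        assert rowland_matin_aucr(x) == pytest.approx(2.0)

    def test_reported_ddi_study_inversion(self):
        # observed AUC ratio 1.76 with half the clearance via the inhibited
        # enzyme implies an unbound-inhibitor/Ki ratio near 6.33
        x = RowlandMartinInputs(fm_total=1.0, fm_cyp1a2=0.5,
                                inhibition_ratio=6.33)
        assert rowland_matin_aucr(x) == pytest.approx(1.76, abs=5e-3)
        assert solve_fm_from_aucr(1.76, 6.33) == pytest.approx(0.50, abs=5e-3)

    def test_inverse_limit_cases(self):
        assert solve_fm_from_aucr(2.0, math.inf) == pytest.approx(0.5)
        assert solve_fm_from_aucr(1.0, 3.0) == 0.0

    @given(st.floats(min_value=0.0, max_value=0.99),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_round_trip_identity(self, q, r):
        x = RowlandMartinInputs(fm_total=q, fm_cyp1a2=1.0, inhibition_ratio=r)
        assert solve_fm_from_aucr(rowland_matin_aucr(x), r) == \
            pytest.approx(q, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            solve_fm_from_aucr(0.8, 3.0)
        with pytest.raises(ValueError):
            solve_fm_from_aucr(1.5, 0.0)


class TestRenalClearance:
    def test_filtration_scales_with_unbound_fraction(self, olz, ref_female):
        no_secretion = olz.with_updates(CL_TSspec=0.0)
        half_bound = no_secretion.with_updates(fu=0.035)
        assert renal_clearance(half_bound, ref_female) == pytest.approx(
            renal_clearance(no_secretion, ref_female) / 2.0)

    def test_secretion_linear_in_kidney_volume(self, olz, ref_female):
        no_filtration = olz.with_updates(GFR_fraction=0.0)
        big = ref_female.copy()
        big.organ_volumes["kidney"] *= 2.0
        assert renal_clearance(no_filtration, big) == pytest.approx(
            2.0 * renal_clearance(no_filtration, ref_female))

    def test_renal_fraction_near_published_anchor(self, olz, baseline_sim):
        breakdown = clearance_breakdown(baseline_sim)
        assert breakdown.renal == pytest.approx(olz.fR_target, abs=0.01)


class TestClearanceBreakdown:
    def test_single_pathway_dominates_when_others_removed(self, ref_female,
                                                          olz):
        cp = olz.with_updates(
            CLint={"CYP1A2": 26.67, "CYP3A4": 0.0, "CYP2C8": 0.0,
                   "FMO3": 0.0, "UGT1A4": 0.0},
            CL_TSspec=0.0, GFR_fraction=0.0)
        model = build_model(ref_female, cp)
        sim = simulate(model, DosingRegimen(dose=10.0), t_end=400.0)
        breakdown = clearance_breakdown(sim)
        assert breakdown.enzyme_fraction("CYP1A2") == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_baseline_fractions_match_in_vivo_anchors(self, baseline_sim,
                                                      olz):
        breakdown = clearance_breakdown(baseline_sim)
        assert breakdown.enzyme_fraction("CYP1A2") == pytest.approx(0.50,
                                                                    abs=0.01)
        assert breakdown.enzyme_fraction("UGT1A4") == pytest.approx(0.23,
                                                                    abs=0.01)

    @pytest.mark.parametrize("dose", [5.0, 20.0])
    def test_fractions_dose_independent(self, ref_female, olz, baseline_sim,
                                        dose):
        model = build_model(ref_female, olz)
        sim = simulate(model, DosingRegimen(dose=dose), t_end=240.0)
        ref = clearance_breakdown(baseline_sim).fractions
        other = clearance_breakdown(sim).fractions
        for pathway in ref:
            assert other[pathway] == pytest.approx(ref[pathway], abs=1e-9)

    def test_common_scaling_preserves_hepatic_ratios(self, ref_female, olz):
        scaled = olz.with_updates(
            CLint={e: 1.7 * v for e, v in olz.CLint.items()})
        m1 = build_model(ref_female, olz)
        m2 = build_model(ref_female, scaled)
        s1 = simulate(m1, DosingRegimen(dose=10.0), t_end=300.0)
        s2 = simulate(m2, DosingRegimen(dose=10.0), t_end=300.0)
        b1, b2 = clearance_breakdown(s1), clearance_breakdown(s2)
        for a, b in (("CYP1A2", "UGT1A4"), ("CYP3A4", "FMO3")):
            r1 = b1.enzyme_fraction(a) / b1.enzyme_fraction(b)
            r2 = b2.enzyme_fraction(a) / b2.enzyme_fraction(b)
            assert r1 == pytest.approx(r2, rel=1e-6)

    def test_fractions_sum_to_one(self, baseline_sim):
        assert sum(clearance_breakdown(baseline_sim).fractions.values()) == \
            pytest.approx(1.0, abs=1e-9)


class TestStaticInhibition:
    def test_identity_half_and_complete(self, olz):
        assert apply_static_inhibition(olz, "CYP1A2", 0.0).CLint == olz.CLint
        assert apply_static_inhibition(olz, "CYP1A2", 1.0).CLint["CYP1A2"] \
            == pytest.approx(26.67 / 2.0)
        assert apply_static_inhibition(olz, "CYP1A2",
                                       math.inf).CLint["CYP1A2"] == 0.0

    def test_unknown_enzyme_rejected(self, olz):
        with pytest.raises(ValueError):
            apply_static_inhibition(olz, "CYP9Z9", 1.0)

    def test_full_cyp1a2_inhibition_doubles_exposure_roughly(
            self, ref_female, olz, baseline_metrics):
        # near-complete inhibition of a 50%-pathway: AUC ratio toward 2
        inhibited = apply_static_inhibition(olz, "CYP1A2", 1e6)
        model = build_model(ref_female, inhibited)
        sim = simulate(model, DosingRegimen(dose=10.0), t_end=400.0)
        from gestpbpk.pk_metrics import nca
        aucr = nca(sim.time, sim.plasma_concentration, 10.0).auc / \
            baseline_metrics.auc
        assert 1.5 < aucr < 2.5
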