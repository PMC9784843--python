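"""Parameter types, scaler tables and population transforms."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import torsemide_pbpk as tp
from torsemide_pbpk.params import (HEALTHY_CYP2C9_ABUNDANCE,
                                   HEALTHY_DRUG, HEALTHY_PHYSIOLOGY)
from torsemide_pbpk.populations import (CHF_TABLE, CIRRHOSIS_TABLE,
                                        CKD_TABLE, CYP2C9_TABLE)


def flow_balanced(phys, rtol=1e-9):
    return (math.isclose(phys.Q_lu, phys.Q_ki + phys.Q_gi + phys.Q_liar + phys.Q_rb,
                         rel_tol=rtol)
            and math.isclose(phys.Q_live, phys.Q_gi + phys.Q_liar, rel_tol=rtol)
            and math.isclose(phys.Q_bl, phys.Q_lu, rel_tol=rtol))


class TestTypes:
    def test_healthy_reference_invariants_and_values(self, healthy):
        phys, drug = healthy
        assert flow_balanced(phys)
        assert phys.hematocrit == 0.43
        assert phys.total_protein == 50.34
        assert drug.F_r == 0.05
        assert drug.P_r == 0.279
        assert all(0 < kp <= 1 for kp in drug.K_p.values())

    def test_flow_imbalance_rejected(self):
        with pytest.raises(ValueError, match="balance"):
            HEALTHY_PHYSIOLOGY.with_(Q_ki=HEALTHY_PHYSIOLOGY.Q_ki * 2)

    def test_hematocrit_bounds(self):
        with pytest.raises(ValueError, match="hematocrit"):
            HEALTHY_PHYSIOLOGY.with_(hematocrit=1.2)

    @pytest.mark.parametrize("field,value", [
        ("K_m", -1.0), ("K_a", 0.0), ("F_r", 1.5), ("P_r", -0.1),
    ])
    def test_drug_invariants(self, field, value):
        with pytest.raises(ValueError):
            HEALTHY_DRUG.with_(**{field: value})


class TestCyp2c9:
    @pytest.mark.parametrize("phenotype,v_max,k_m", [
        ("EM", 2.216, 1.951), ("IM", 0.886, 5.073), ("PM", 0.222, 8.242),
    ])
    def test_table_values(self, phenotype, v_max, k_m):
        drug = tp.apply_cyp2c9(HEALTHY_DRUG, phenotype)
        assert drug.V_max == v_max and drug.K_m == k_m
        # all other fields untouched
        assert drug.K_a == HEALTHY_DRUG.K_a and drug.K_p == HEALTHY_DRUG.K_p

    def test_unknown_phenotype(self):
        with pytest.raises(ValueError, match="phenotype"):
            tp.apply_cyp2c9(HEALTHY_DRUG, "UM")

    def test_intrinsic_clearance(self):
        assert tp.intrinsic_clearance(HEALTHY_DRUG.with_(V_max=2.216, K_m=1.951)) \
            == pytest.approx(1.1358, abs=1e-4)
        assert tp.intrinsic_clearance(HEALTHY_DRUG.with_(V_max=0.0, K_m=5.0)) == 0.0
        assert tp.intrinsic_clearance(HEALTHY_DRUG.with_(V_max=3.0, K_m=3.0)) == 1.0

    def test_stepwise_clearance_reduction_ratio(self):
        """Successive phenotype steps each cut intrinsic clearance ~0.15x."""
        cl = {ph: v / k for ph, (v, k) in CYP2C9_TABLE.items()}
        assert cl["IM"] / cl["EM"] == pytest.approx(0.154, abs=5e-4)
        assert round(cl["IM"] / cl["EM"], 2) == 0.15
        assert round(cl["PM"] / cl["IM"], 2) == 0.15


class TestBindingRescaling:
    def test_fr_identity_at_equal_protein(self):
        assert tp.fr_diseased(0.05, 50.34, 50.34) == pytest.approx(0.05, rel=1e-12)

    @pytest.mark.parametrize("pt_dis,expected", [
        (29.69, 0.08193), (46.33, 0.05409),
    ])
    def test_fr_values(self, pt_dis, expected):
        assert tp.fr_diseased(0.05, 50.34, pt_dis) == pytest.approx(expected, abs=5e-5)

    @given(pt=st.floats(1.0, 200.0))
    @settings(deadline=None, max_examples=50)
    def test_fr_in_unit_interval(self, pt):
        fr = tp.fr_diseased(0.05, 50.34, pt)
        assert 0.0 < fr <= 1.0

    @given(pt_lo=st.floats(1.0, 200.0), delta=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_fr_monotone_decreasing_in_protein(self, pt_lo, delta):
        assert tp.fr_diseased(0.05, 50.34, pt_lo) > tp.fr_diseased(0.05, 50.34,
                                                                   pt_lo + delta)

    def test_fr_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tp.fr_diseased(0.05, 50.34, 0.0)

    @pytest.mark.parametrize("hct_dis,expected", [
        (0.3351, 0.2174), (0.3846, 0.2495),
    ])
    def test_pr_values(self, hct_dis, expected):
        assert tp.pr_diseased(0.279, 0.43, hct_dis) == pytest.approx(expected, abs=5e-5)

    def test_pr_identity_and_errors(self):
        assert tp.pr_diseased(0.279, 0.43, 0.43) == pytest.approx(0.279)
        with pytest.raises(ValueError):
            tp.pr_diseased(0.279, 0.0, 0.4)


class TestCirrhosis:
    def test_cp_b_vmax_via_cyp_abundance(self, healthy):
        phys, drug = healthy
        _, d2 = tp.apply_cirrhosis(phys, drug, "B")
        assert d2.V_max == pytest.approx(2.216 * 38.0 / 73.0, rel=1e-12)
        assert d2.V_max == pytest.approx(1.1535, abs=1e-4)

    def test_liver_volume_and_cyp_decrease_a_to_c(self):
        a, c = CIRRHOSIS_TABLE["CP-A"], CIRRHOSIS_TABLE["CP-C"]
        lv = (a["liver_volume_fraction"] - c["liver_volume_fraction"]) \
            / a["liver_volume_fraction"]
        cyp = (a["cyp2c9_pmol_per_mg"] - c["cyp2c9_pmol_per_mg"]) \
            / a["cyp2c9_pmol_per_mg"]
        assert lv * 100 == pytest.approx(34.57, abs=0.01)
        assert cyp * 100 == pytest.approx(52.18, abs=0.01)

    @pytest.mark.parametrize("cls", ["A", "B", "C"])
    def test_transform_consistency(self, healthy, cls):
        phys, drug = healthy
        p2, d2 = tp.apply_cirrhosis(phys, drug, cls)
        t = CIRRHOSIS_TABLE[f"CP-{cls}"]
        assert flow_balanced(p2)
        assert p2.V_li == pytest.approx(phys.V_li * t["liver_volume_fraction"])
        assert p2.Q_lu == pytest.approx(phys.Q_lu * t["cardiac_output_fraction"])
        assert p2.hematocrit == pytest.approx(t["hematocrit_pct"] / 100)
        assert p2.total_protein == t["total_protein_g_per_L"]
        assert p2.Q_rb > 0
        assert d2.K_e == pytest.approx(drug.K_e * t["villous_blood_flow_fraction"])
        assert d2.F_r == pytest.approx(
            tp.fr_diseased(drug.F_r, phys.total_protein, t["total_protein_g_per_L"]))
        assert d2.P_r == pytest.approx(
            tp.pr_diseased(drug.P_r, phys.hematocrit, t["hematocrit_pct"] / 100))
        for tissue, kp in drug.K_p.items():
            assert d2.K_p[tissue] == pytest.approx(kp * t["kp_multiplier"])
        # untouched constants
        assert (d2.K_a, d2.K_u, d2.K_m) == (drug.K_a, drug.K_u, drug.K_m)

    def test_unknown_class(self, healthy):
        with pytest.raises(ValueError, match="Child-Pugh"):
            tp.apply_cirrhosis(*healthy, "D")


class TestCkd:
    def test_severe_renal_rate(self, healthy):
        phys, drug = healthy
        _, d2 = tp.apply_ckd(phys, drug, "severe")
        assert d2.K_u == pytest.approx(drug.K_u * 0.37)

    def test_moderate_intrinsic_clearance_fraction(self, healthy):
        phys, drug = healthy
        _, d2 = tp.apply_ckd(phys, drug, "moderate")
        assert tp.intrinsic_clearance(d2) / tp.intrinsic_clearance(drug) \
            == pytest.approx(0.69, rel=1e-12)

    def test_mild_flow_compensation(self, healthy):
        phys, drug = healthy
        p2, _ = tp.apply_ckd(phys, drug, "mild")
        assert p2.Q_ki == pytest.approx(phys.Q_ki * 0.99)
        assert p2.Q_rb - phys.Q_rb == pytest.approx(0.01 * phys.Q_ki)
        assert p2.Q_lu == pytest.approx(phys.Q_lu)  # total preserved
        assert flow_balanced(p2)

    def test_unknown_stage(self, healthy):
        with pytest.raises(ValueError, match="CKD"):
            tp.apply_ckd(*healthy, "terminal")


class TestChf:
    def test_moderate_vmax(self, healthy):
        phys, drug = healthy
        _, d2 = tp.apply_chf(phys, drug, "moderate")
        assert d2.V_max == pytest.approx(drug.V_max * 0.54)

    def test_severe_kidney_flow(self, healthy):
        phys, drug = healthy
        p2, _ = tp.apply_chf(phys, drug, "severe")
        assert p2.Q_ki == pytest.approx(phys.Q_ki * 0.63)
        assert flow_balanced(p2)

    def test_total_flow_is_regional_sum(self, healthy):
        phys, drug = healthy
        t = CHF_TABLE["moderate"]
        p2, _ = tp.apply_chf(phys, drug, "moderate")
        expected = (phys.Q_ki * t["kidney_blood_flow_fraction"]
                    + phys.Q_gi * t["portal_blood_flow_fraction"]
                    + phys.Q_liar * t["hepatic_arterial_blood_flow_fraction"]
                    + phys.Q_rb * t["other_tissues_blood_flow_fraction"])
        assert p2.Q_lu == pytest.approx(expected, rel=1e-12)


class TestTables:
    """Shipped scaler tables reproduce the published cells exactly."""

    @pytest.mark.parametrize("cls,key,value", [
        ("CP-A", "kidney_blood_flow_fraction", 0.70),
        ("CP-B", "portal_blood_flow_fraction", 0.63),
        ("CP-C", "villous_blood_flow_fraction", 1.99),
        ("CP-C", "hematocrit_pct", 33.51),
        ("CP-A", "total_protein_g_per_L", 46.33),
        ("CP-B", "cyp2c9_pmol_per_mg", 38.0),
    ])
    def test_cirrhosis_cells(self, cls, key, value):
        assert CIRRHOSIS_TABLE[cls][key] == value

    @pytest.mark.parametrize("stage,key,value", [
        ("mild", "renal_elimination_rate_fraction", 0.99),
        ("moderate", "liver_intrinsic_clearance_fraction", 0.69),
        ("severe", "kidney_volume_fraction", 0.87),
        ("severe", "kidney_blood_flow_fraction", 0.72),
    ])
    def test_ckd_cells(self, stage, key, value):
        assert CKD_TABLE[stage][key] == value

    @pytest.mark.parametrize("stage,key,value", [
        ("mild", "cardiac_output_fraction", 0.69),
        ("moderate", "other_tissues_blood_flow_fraction", 0.44),
        ("severe", "liver_intrinsic_clearance_fraction", 0.46),
        ("severe", "kidney_blood_flow_fraction", 0.63),
    ])
    def test_chf_cells(self, stage, key, value):
        assert CHF_TABLE[stage][key] == value

    def test_healthy_cyp_abundance(self):
        assert HEALTHY_CYP2C9_ABUNDANCE == 73.0


class TestResolve:
    @pytest.mark.parametrize("label", tp.POPULATION_LABELS)
    def test_all_labels_resolve_and_balance(self, label):
        phys, drug = tp.resolve_population(label)
        assert flow_balanced(phys)
        assert drug.V_max > 0

    def test_unknown_label_lists_valid(self):
        with pytest.raises(ValueError, match="healthy"):
            tp.resolve_population("martian")

    def test_healthy_is_identity(self, healthy):
        phys, drug = tp.resolve_population("healthy")
        assert phys == healthy[0] and drug == healthy[1]
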