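"""ODE right-hand side, integrator contract, and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import torsemide_pbpk as tp
from torsemide_pbpk.model import MG_TO_UG, STATE_NAMES
from torsemide_pbpk.model import rhs as model_rhs


class TestRhs:
    def test_zero_state_zero_derivatives(self, healthy):
        assert np.all(model_rhs(np.zeros(10), *healthy) == 0.0)

    def test_half_saturation_metabolic_rate(self, healthy):
        """At unbound hepatic concentration equal to Km the metabolic loss
        is exactly Vmax*V_li/2."""
        phys, drug = healthy
        # choose liver amount so C_u = F_r * A_li/(V_li*K_li) == K_m
        a_li = drug.K_m * phys.V_li * drug.K_p["liver"] / drug.F_r
        state = np.zeros(10)
        state[STATE_NAMES.index("liver")] = a_li
        derivs = model_rhs(state, phys, drug)
        metab_rate = derivs[STATE_NAMES.index("metabolized")]
        assert metab_rate == pytest.approx(drug.V_max * phys.V_li / 2.0, rel=1e-12)

    @given(st.lists(st.floats(0.0, 1e5), min_size=7, max_size=7))
    @settings(deadline=None, max_examples=50)
    def test_mass_conservation_of_derivatives(self, healthy, amounts):
        """Including the sinks, the state derivatives sum to zero."""
        phys, drug = healthy
        state = np.zeros(10)
        state[:7] = amounts
        derivs = model_rhs(state, phys, drug)
        scale = max(np.abs(derivs).max(), 1.0)
        assert abs(derivs.sum()) <= 1e-9 * scale

    def test_negative_state_rejected(self, healthy):
        state = np.zeros(10)
        state[1] = -100.0
        with pytest.raises(ValueError, match="negative"):
            model_rhs(state, *healthy)


class TestPlasmaConversion:
    def test_homogeneous_blood(self):
        assert tp.plasma_from_blood(0.5, 0.43, 1.0) == pytest.approx(0.5)
        assert tp.plasma_from_blood(0.5, 0.0, 0.279) == pytest.approx(0.5)

    def test_reference_value(self):
        assert tp.plasma_from_blood(0.690, 0.43, 0.279) == pytest.approx(1.000, abs=1e-3)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            tp.plasma_from_blood(1.0, 1.0, 0.0)


class TestUrinaryRate:
    def test_values(self):
        assert tp.urinary_excretion_rate(0.0, 0.1) == 0.0
        assert tp.urinary_excretion_rate(500.0, 0.1) == pytest.approx(50.0)

    def test_rate_integrates_to_cumulative_urine(self, traj_10mg_oral):
        traj = traj_10mg_oral
        integral = np.trapezoid(traj.x, traj.times)
        assert integral == pytest.approx(traj.A_u[-1], rel=1e-3)


class TestSimulate:
    def test_zero_doses_zero_trajectory(self, healthy):
        phys, drug = healthy
        spec = tp.SimulationSpec(physiology=phys, drug=drug, doses=[],
                                 t_end=12.0, output_grid=np.linspace(0, 12, 13))
        traj = tp.simulate(spec)
        assert np.all(traj.C_plasma == 0.0) and np.all(traj.A_u == 0.0)

    def test_mass_balance_and_nonnegativity(self, traj_10mg_oral):
        assert np.abs(traj_10mg_oral.mass_balance_error()).max() <= 1e-6
        for series in traj_10mg_oral.amounts.values():
            assert np.all(series >= -1e-8)

    def test_iv_bolus_fully_recovered_in_urine_without_losses(self, healthy):
        """With metabolism and GI loss off, urine eventually recovers the
        entire IV dose."""
        phys, drug = healthy
        drug = drug.with_(V_max=0.0, K_e=0.0)
        spec = tp.single_dose_spec(phys, drug, 10.0, route="iv_bolus",
                                   t_end=120.0, n_points=121)
        traj = tp.simulate(spec)
        assert traj.A_u[-1] == pytest.approx(10.0 * MG_TO_UG, rel=1e-4)

    def test_dose_linearity_exact_without_metabolism(self, healthy):
        phys, drug = healthy
        drug = drug.with_(V_max=0.0)
        t1 = tp.simulate(tp.single_dose_spec(phys, drug, 10.0, t_end=24.0))
        t2 = tp.simulate(tp.single_dose_spec(phys, drug, 20.0, t_end=24.0))
        mask = t1.C_plasma > 1e-9
        assert np.allclose(t2.C_plasma[mask] / t1.C_plasma[mask], 2.0, rtol=1e-6)

    def test_tolerance_refinement_stable(self, healthy):
        phys, drug = healthy
        coarse = tp.simulate(tp.single_dose_spec(phys, drug, 10.0, t_end=24.0,
                                                 rel_tol=1e-8, abs_tol=1e-10))
        fine = tp.simulate(tp.single_dose_spec(phys, drug, 10.0, t_end=24.0,
                                               rel_tol=1e-9, abs_tol=1e-11))
        mask = fine.C_plasma > 1e-6 * fine.C_plasma.max()
        rel = np.abs(coarse.C_plasma[mask] - fine.C_plasma[mask]) / fine.C_plasma[mask]
        assert rel.max() < 1e-3

    def test_matches_fixed_step_rk4_oracle(self, healthy):
        """Adaptive LSODA agrees with a fixed-step RK4 integration."""
        phys, drug = healthy
        h = 0.001
        n_steps = 24000
        y = np.zeros(10)
        y[0] = 10.0 * MG_TO_UG  # oral depot
        record_every = 1000     # each hour
        rec = [y.copy()]
        for i in range(n_steps):
            k1 = model_rhs(y, phys, drug)
            k2 = model_rhs(y + 0.5 * h * k1, phys, drug)
            k3 = model_rhs(y + 0.5 * h * k2, phys, drug)
            k4 = model_rhs(y + h * k3, phys, drug)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if (i + 1) % record_every == 0:
                rec.append(y.copy())
        rk4_blood = np.array([r[1] for r in rec])

        spec = tp.single_dose_spec(phys, drug, 10.0, t_end=24.0, n_points=25)
        traj = tp.simulate(spec)
        mask = rk4_blood > 1e-6 * rk4_blood.max()
        rel = np.abs(traj.amounts["blood"][mask] - rk4_blood[mask]) / rk4_blood[mask]
        assert rel.max() < 5e-3

    def test_iv_auc_exceeds_oral_auc_with_gi_loss(self, healthy):
        phys, drug = healthy
        assert drug.K_e > 0
        oral = tp.simulate(tp.single_dose_spec(phys, drug, 10.0, "oral", t_end=48.0))
        iv = tp.simulate(tp.single_dose_spec(phys, drug, 10.0, "iv_bolus", t_end=48.0))
        auc_oral = tp.nca(oral.times, oral.C_plasma).AUC_0_inf
        auc_iv = tp.nca(iv.times, iv.C_plasma).AUC_0_inf
        assert auc_iv > auc_oral

    def test_spec_validation(self, healthy):
        phys, drug = healthy
        with pytest.raises(ValueError, match="t_end"):
            tp.SimulationSpec(physiology=phys, drug=drug,
                              doses=[tp.DoseEvent(30.0, 1000.0, "oral")],
                              t_end=24.0, output_grid=np.linspace(0, 24, 10))
        with pytest.raises(ValueError, match="increasing"):
            tp.SimulationSpec(physiology=phys, drug=drug, doses=[],
                              t_end=24.0, output_grid=np.array([0.0, 5.0, 5.0]))

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            tp.DoseEvent(time=0.0, amount=-1.0, route="oral")
        with pytest.raises(ValueError):
            tp.DoseEvent(time=0.0, amount=1.0, route="sublingual")
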