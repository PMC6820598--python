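import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dense_scan_tat2, ode_profile
from fviiipk.structural_pk import (
    BaselineSpec,
    DispositionParams,
    DoseEvent,
    MacroDisposition,
    full_profile,
    infusion_concentration,
    micro_to_macro,
    terminal_half_life,
    time_above_threshold,
)


class TestMicroToMacro:
    def test_one_compartment_single_exponential(self):
        m = micro_to_macro(DispositionParams(CL=0.195, V1=2.30))
        assert len(m.coefficients) == 1
        amp, rate = m.coefficients[0]
        assert amp == pytest.approx(1 / 2.30)
        assert rate == pytest.approx(0.195 / 2.30)
        assert rate == pytest.approx(0.08478, abs=1e-5)

    @pytest.mark.parametrize("cl,v1,q,v2", [
        (0.195, 2.30, 0.078, 0.449),
        (0.5, 5.0, 0.2, 1.5),
        (0.05, 1.0, 0.01, 0.1),
    ])
    def test_initial_condition_identities(self, cl, v1, q, v2):
        p = DispositionParams(CL=cl, V1=v1, Q=q, V2=v2)
        m = micro_to_macro(p)
        (A, alpha), (B, beta) = m.coefficients
        assert alpha > beta > 0
        assert A + B == pytest.approx(1 / v1, rel=1e-12)
        k10, k12 = cl / v1, q / v1
        assert alpha * A + beta * B == pytest.approx((k10 + k12) / v1, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DispositionParams(CL=-0.1, V1=2.0)
        with pytest.raises(ValueError):
            DispositionParams(CL=0.2, V1=2.0, Q=0.1, V2=None)
        with pytest.raises(ValueError):
            MacroDisposition(((0.4, 0.1), (0.3, 0.2)))  # rates not descending

    @settings(max_examples=25, deadline=None)
    @given(
        cl=st.floats(0.02, 1.0),
        v1=st.floats(0.5, 10.0),
        q=st.floats(0.01, 0.5),
        v2=st.floats(0.1, 3.0),
    )
    def test_bolus_profile_matches_ode(self, cl, v1, q, v2):
        """Closed-form biexponential equals mass-balance integration."""
        p = DispositionParams(CL=cl, V1=v1, Q=q, V2=v2)
        m = micro_to_macro(p)
        doses = [DoseEvent(2000.0, 0.0, 0.0)]
        t = np.array([0.5, 6.0, 24.0, 72.0, 168.0])
        closed = np.asarray(infusion_concentration(m, doses, t))
        ode = ode_profile(p, doses, t)
        # atol far below the assay LLOQ covers the integrator's noise floor
        np.testing.assert_allclose(closed, ode, rtol=1e-6, atol=1e-12)

    def test_table_model_infusion_matches_ode(self, table_params, table_macro):
        doses = [DoseEvent(2000.0, 0.0, 0.25)]
        t = np.array([0.1, 0.2, 0.5, 6.0, 24.0, 72.0])
        closed = np.asarray(infusion_concentration(table_macro, doses, t))
        ode = ode_profile(table_params, doses, t)
        np.testing.assert_allclose(closed, ode, rtol=1e-7)


class TestInfusionConcentration:
    def test_zero_dose_and_pre_dose_times(self, table_macro):
        doses = [DoseEvent(0.0, 0.0, 0.25)]
        assert infusion_concentration(table_macro, doses, 5.0) == 0.0
        doses = [DoseEvent(2000.0, 10.0, 0.25)]
        assert infusion_concentration(table_macro, doses, 5.0) == 0.0

    def test_bolus_initial_concentration(self, table_macro):
        c0 = infusion_concentration(table_macro, [DoseEvent(2000.0, 0.0, 0.0)], 0.0)
        assert c0 == pytest.approx(2000.0 / 2.30 / 1000.0, rel=1e-12)
        assert c0 == pytest.approx(0.8696, abs=1e-4)

    def test_superposition(self, table_macro):
        d1 = [DoseEvent(1500.0, 0.0, 0.25)]
        d2 = [DoseEvent(800.0, 24.0, 0.5)]
        t = np.linspace(0.0, 96.0, 40)
        both = np.asarray(infusion_concentration(table_macro, d1 + d2, t))
        sep = np.asarray(infusion_concentration(table_macro, d1, t)) + np.asarray(
            infusion_concentration(table_macro, d2, t)
        )
        np.testing.assert_allclose(both, sep, rtol=1e-12)

    def test_terminal_slope_approaches_beta(self, table_macro):
        """After 5/alpha the log-profile decays at the terminal rate."""
        doses = [DoseEvent(2000.0, 0.0, 0.25)]
        alpha = table_macro.rates[0]
        beta = table_macro.terminal_rate
        t = np.linspace(5 / alpha + 24, 5 / alpha + 96, 50)
        vals = np.log(np.asarray(infusion_concentration(table_macro, doses, t)))
        slopes = np.diff(vals) / np.diff(t)
        assert np.all(np.diff(np.asarray(infusion_concentration(table_macro, doses, t))) < 0)
        np.testing.assert_allclose(slopes, -beta, rtol=1e-3)


class TestFullProfile:
    def test_no_dose_constant_endogenous(self, table_macro):
        b = BaselineSpec(endogenous=0.005)
        t = np.array([0.0, 10.0, 100.0])
        np.testing.assert_allclose(full_profile(table_macro, [], b, t), 0.005)

    def test_predose_equal_endogenous_no_residual(self, table_macro):
        b1 = BaselineSpec(endogenous=0.02, predose=0.02, predose_time=-1.0)
        b2 = BaselineSpec(endogenous=0.02)
        doses = [DoseEvent(1000.0, 0.0, 0.25)]
        t = np.linspace(0, 72, 20)
        np.testing.assert_allclose(
            full_profile(table_macro, doses, b1, t), full_profile(table_macro, doses, b2, t)
        )

    def test_predose_residual_halves_per_terminal_half_life(self, table_macro):
        b = BaselineSpec(endogenous=0.005, predose=0.05, predose_time=0.0)
        hl = terminal_half_life(table_macro)
        value = full_profile(table_macro, [], b, hl)
        # residual (0.05 - 0.005) halves to 0.0225, plus the endogenous level
        assert value == pytest.approx(0.0225 + 0.005, rel=1e-12)

    def test_negative_residual_floored_at_zero(self, table_macro):
        b = BaselineSpec(endogenous=0.01, predose=0.0, predose_time=0.0)
        v = full_profile(table_macro, [], b, 0.0)
        assert v == 0.0
        assert full_profile(table_macro, [], b, 0.0, floor=False) == pytest.approx(0.0, abs=1e-15)


class TestTerminalHalfLife:
    def test_closed_forms(self):
        m1 = micro_to_macro(DispositionParams(CL=0.195, V1=2.30))
        assert terminal_half_life(m1) == pytest.approx(np.log(2) * 2.30 / 0.195, rel=1e-12)
        assert terminal_half_life(m1) == pytest.approx(8.17, abs=0.01)
        m2 = MacroDisposition(((0.3, 0.5), (0.2, 0.05)))
        assert terminal_half_life(m2) == pytest.approx(np.log(2) / 0.05, rel=1e-12)

    def test_half_life_proportional_to_volume(self):
        m1 = micro_to_macro(DispositionParams(CL=0.2, V1=2.0))
        m2 = micro_to_macro(DispositionParams(CL=0.2, V1=4.0))
        assert terminal_half_life(m2) == pytest.approx(2 * terminal_half_life(m1), rel=1e-12)


class TestTimeAboveThreshold:
    def test_trivial_cases(self, table_macro):
        no_dose = BaselineSpec(endogenous=0.005)
        assert time_above_threshold(table_macro, [], no_dose, 0.02, horizon=168.0) == 0.0
        high = BaselineSpec(endogenous=0.03)
        assert time_above_threshold(table_macro, [], high, 0.02, horizon=168.0) == 168.0

    def test_against_dense_grid_scan(self, table_macro):
        b = BaselineSpec(endogenous=0.005)
        doses = [DoseEvent(2000.0, 0.0, 0.25)]
        got = time_above_threshold(table_macro, doses, b, 0.02, horizon=168.0, dt=0.1)
        want = dense_scan_tat2(table_macro, doses, b, 0.02, horizon=168.0, dt=0.001)
        assert got == pytest.approx(want, abs=0.05)
        assert 24.0 < got < 168.0

    def test_monotone_in_dose_and_threshold(self, table_macro):
        b = BaselineSpec(endogenous=0.005)
        tat = [
            time_above_threshold(table_macro, [DoseEvent(a, 0.0, 0.25)], b, 0.02, horizon=168.0)
            for a in (500.0, 1000.0, 2000.0, 4000.0)
        ]
        assert all(t1 <= t2 for t1, t2 in zip(tat, tat[1:]))
        thr = [
            time_above_threshold(table_macro, [DoseEvent(2000.0, 0.0, 0.25)], b, th, horizon=168.0)
            for th in (0.01, 0.02, 0.05, 0.2)
        ]
        assert all(t1 >= t2 for t1, t2 in zip(thr, thr[1:]))
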