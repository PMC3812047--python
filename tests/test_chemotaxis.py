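import dataclasses

import numpy as np
import pytest

from protoadapt.chemotaxis import (
    ChemotaxisParams,
    ChemotaxisState,
    adapted_methylation,
    dmdt_equilibrium,
    dmdt_mixed,
    dmdt_precise,
    entropy_rate_bc,
    equilibrium_methylation,
    integrate_response,
    precision_dissipation_sweep,
    receptor_activity_bc,
    steady_state_m,
)
from protoadapt.config import StepStimulus


@pytest.fixture
def params() -> ChemotaxisParams:
    return ChemotaxisParams()


class TestActivity:
    def test_half_activity_at_zero_free_energy(self, params):
        # eps0 + eps1*m = 0 at m = 2 for the default eps(m) = 1 - m/2, c = 0
        assert receptor_activity_bc(2.0, 0.0, params) == pytest.approx(0.5)

    def test_attractant_saturation_silences_the_receptor(self, params):
        assert receptor_activity_bc(5.0, 1e6, params) < 1e-3

    def test_monotone_in_methylation_and_stimulus(self, params):
        m = np.linspace(0, 8, 50)
        a = receptor_activity_bc(m, 0.1, params)
        assert np.all(np.diff(a) > 0)
        c = np.geomspace(1e-3, 10, 50)
        a = receptor_activity_bc(4.0, c, params)
        assert np.all(np.diff(a) < 0)

    def test_adapted_methylation_restores_the_set_point(self, params):
        for c in [0.01, 0.1, 1.0]:
            m_star = adapted_methylation(c, params)
            assert receptor_activity_bc(m_star, c, params) == pytest.approx(
                params.set_point, abs=1e-12
            )


class TestPreciseDynamics:
    def test_fixed_point_at_the_set_point(self, params):
        assert dmdt_precise(4.0, params.set_point, params) == pytest.approx(0.0)

    def test_negative_feedback_sign(self, params):
        assert dmdt_precise(4.0, params.set_point + 0.1, params) < 0
        assert dmdt_precise(4.0, params.set_point - 0.1, params) > 0

    def test_step_response_returns_to_set_point(self, params):
        m0 = steady_state_m(0.1, 0.0, params)
        t = np.linspace(0, 3000, 400)
        c_of_t = lambda s: 0.1 if s < 10 else 0.2
        m, a = integrate_response(c_of_t, m0, t, 0.0, params)
        i_step = np.searchsorted(t, 10.0)
        assert a[i_step + 1] < params.set_point  # transient drop on attractant
        assert a[-1] == pytest.approx(params.set_point, abs=1e-7)


class TestEquilibriumDynamics:
    def test_steady_state_depends_on_stimulus(self, params):
        m_lo = equilibrium_methylation(0.05, params)
        m_hi = equilibrium_methylation(0.5, params)
        assert m_hi > m_lo  # imprecise: adapted state shifts with c

    def test_root_confirmed_by_long_integration(self, params):
        c = 0.2
        m_eq = equilibrium_methylation(c, params)
        t = np.linspace(0, 5000, 50)
        m, _ = integrate_response(lambda s: c, m_eq + 1.0, t, 1.0, params, rtol=1e-10)
        assert abs(m[-1] - m_eq) < 1e-8

    def test_zero_entropy_production_at_equilibrium(self, params):
        assert params.satisfies_equilibration()
        c = 0.2
        m_eq = equilibrium_methylation(c, params)
        a = receptor_activity_bc(m_eq, c, params)
        s = entropy_rate_bc(ChemotaxisState(0.0, m_eq, a, c), 1.0, params)
        assert abs(s) < 1e-20

    def test_violated_equilibration_condition_dissipates(self, params):
        bad = dataclasses.replace(params, beta_plus=2 * params.beta_plus)
        assert not bad.satisfies_equilibration()
        c = 0.2
        m_ss = steady_state_m(c, 1.0, bad)
        a = receptor_activity_bc(m_ss, c, bad)
        assert entropy_rate_bc(ChemotaxisState(0.0, m_ss, a, c), 1.0, bad) > 1e-3


class TestMixture:
    def test_endpoint_reductions_and_convexity(self, params):
        m, c = 4.5, 0.2
        a = receptor_activity_bc(m, c, params)
        assert dmdt_mixed(m, a, c, 0.0, params) == dmdt_precise(m, a, params)
        assert dmdt_mixed(m, a, c, 1.0, params) == dmdt_equilibrium(m, c, params)
        mid = dmdt_mixed(m, a, c, 0.5, params)
        assert mid == pytest.approx(
            0.5 * (dmdt_precise(m, a, params) + dmdt_equilibrium(m, c, params))
        )

    def test_x_outside_unit_interval_rejected(self, params):
        with pytest.raises(ValueError):
            dmdt_mixed(4.0, 0.3, 0.2, 1.5, params)

    def test_futile_cycle_dissipates_at_x_zero(self, params):
        c = 0.2
        m_ss = steady_state_m(c, 0.0, params)
        a = receptor_activity_bc(m_ss, c, params)
        s = entropy_rate_bc(ChemotaxisState(0.0, m_ss, a, c), 0.0, params)
        assert s > 1.0  # k_B/s for ~1e4 receptors: strictly positive

    def test_entropy_scales_linearly_with_receptor_count(self, params):
        c = 0.2
        m_ss = steady_state_m(c, 0.0, params)
        a = receptor_activity_bc(m_ss, c, params)
        s1 = entropy_rate_bc(ChemotaxisState(0.0, m_ss, a, c), 0.0, params)
        double = dataclasses.replace(params, N_rec=2 * params.N_rec)
        s2 = entropy_rate_bc(ChemotaxisState(0.0, m_ss, a, c), 0.0, double)
        assert s2 == pytest.approx(2 * s1)


class TestTradeOffSweep:
    def test_dissipation_falls_and_imprecision_rises_with_x(self, params):
        x = [0.0, 0.25, 0.5, 0.75, 1.0]
        tab = precision_dissipation_sweep(x, StepStimulus(c0=0.1, c1=0.2), params)
        assert np.all(np.diff(tab.entropy_rate) < 0)
        assert np.all(np.diff(tab.imprecision) > 0)
        assert tab.imprecision.iloc[0] < 1e-6  # precise endpoint
        assert tab.entropy_rate.iloc[-1] < 1e-10 * tab.entropy_rate.iloc[0]

    def test_sweep_rejects_invalid_inputs(self, params):
        with pytest.raises(ValueError):
            precision_dissipation_sweep([0.0, 2.0], StepStimulus(0.1, 0.2), params)
        with pytest.raises(ValueError):
            precision_dissipation_sweep([0.0], StepStimulus(0.0, 0.2), params)
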