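import numpy as np
import pytest
from hypothesis import given, strategies as st

from protoadapt.config import (
    ReceptorParams,
    SimulationConfig,
    SolverSettings,
    StepStimulus,
)
from protoadapt.metrics import adaptation_time, fcd_distance, response_time
from protoadapt.one_component import (
    activity,
    detailed_balance_report,
    free_energy,
    simulate_step,
)


class TestFreeEnergy:
    def test_no_ligand_limit_is_the_bias(self, receptor):
        assert free_energy(0.0, 0.0, receptor) == pytest.approx(receptor.epsilon)
        biased = ReceptorParams(epsilon=1.7)
        assert free_energy(0.0, 0.0, biased) == pytest.approx(1.7)

    def test_matched_concentrations_return_baseline_under_symmetric_constants(
        self, receptor
    ):
        # the analytic root of precise adaptation: the external and internal
        # binding terms cancel exactly when c_in == c_out
        for c in [1e-4, 0.01, 0.5, 3.0, 80.0, 1e3]:
            assert free_energy(c, c, receptor) == pytest.approx(
                receptor.epsilon, abs=1e-12
            )

    def test_monotone_in_both_arguments(self, receptor):
        c = np.geomspace(1e-3, 1e3, 40)
        for c_in in (0.0, 0.1, 10.0):
            F = free_energy(c, np.full_like(c, c_in), receptor)
            assert np.all(np.diff(F) > 0)  # increasing in c_out
        for c_out in (0.0, 0.1, 10.0):
            F = free_energy(np.full_like(c, c_out), c, receptor)
            assert np.all(np.diff(F) < 0)  # decreasing in c_in

    def test_invalid_inputs(self, receptor):
        with pytest.raises(ValueError):
            free_energy(-1.0, 0.0, receptor)
        with pytest.raises(ValueError):
            free_energy(np.inf, 0.0, receptor)


class TestActivity:
    def test_symmetric_point_and_saturation(self):
        assert activity(0.0) == pytest.approx(0.5)
        assert activity(800.0) == pytest.approx(0.0, abs=1e-300)
        assert activity(-800.0) == pytest.approx(1.0)

    @given(st.floats(-50, 50))
    def test_logistic_symmetry(self, F):
        assert activity(F) + activity(-F) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing(self):
        F = np.linspace(-30, 30, 500)
        assert np.all(np.diff(activity(F)) < 0)


class TestSimulateStep:
    def test_zero_step_gives_flat_activity(self, step_config):
        cfg = step_config.replace(stimulus=StepStimulus(c0=1.0, c1=1.0, t_step=0.05))
        traj = simulate_step(cfg)
        assert np.ptp(traj.activity) == 0.0

    def test_positive_step_drops_then_recovers_precisely(self, step_config):
        traj = simulate_step(step_config)
        i0 = np.searchsorted(traj.t, 0.05)
        a_pre = traj.activity[i0 - 1]
        assert traj.activity[i0] < a_pre  # activity drops at the step
        assert traj.activity.min() == traj.activity[i0]
        assert abs(traj.activity[-1] - a_pre) < 1e-6  # precise adaptation

    def test_interior_concentration_equilibrates_to_stimulus(self, step_config):
        traj = simulate_step(step_config)
        assert traj.c_in[0] == 1.0
        assert traj.c_in[-1] == pytest.approx(1.5, abs=1e-9)

    @pytest.mark.parametrize("c0", [0.01, 0.1, 1.0, 10.0, 100.0])
    @pytest.mark.parametrize("fold", [1.1, 2.0, 10.0])
    def test_precise_adaptation_across_backgrounds_and_folds(self, step_config, c0, fold):
        cfg = step_config.replace(stimulus=StepStimulus(c0=c0, c1=fold * c0, t_step=0.05))
        traj = simulate_step(cfg)
        assert abs(traj.activity[-1] - traj.activity[0]) < 1e-6

    def test_response_is_instantaneous(self, step_config):
        traj = simulate_step(step_config)
        assert response_time(traj, 0.05) <= step_config.solver.dt

    def test_negative_step_to_zero_concentration_allowed(self, step_config):
        cfg = step_config.replace(stimulus=StepStimulus(c0=1.0, c1=0.0, t_step=0.05))
        traj = simulate_step(cfg)
        assert traj.activity.max() > traj.activity[0]
        assert abs(traj.activity[-1] - traj.activity[0]) < 1e-6


class TestFoldChangeDetection:
    @pytest.mark.parametrize("lam", [2.0, 5.0])
    def test_rescaled_steps_superimpose(self, step_config, lam):
        # both concentrations well above the tight K (0.01) and below the
        # weak K (100): the free energy is a function of the fold alone
        sol = SolverSettings(dt=1e-4, t_end=0.5)
        base = step_config.replace(
            stimulus=StepStimulus(c0=0.2, c1=0.6, t_step=0.01), solver=sol
        )
        scaled = step_config.replace(
            stimulus=StepStimulus(c0=0.2 * lam, c1=0.6 * lam, t_step=0.01), solver=sol
        )
        d = fcd_distance(simulate_step(base), simulate_step(scaled), 0.01, 0.01)
        assert d < 1e-2

    def test_different_folds_are_distinguished(self, step_config):
        sol = SolverSettings(dt=1e-4, t_end=0.5)
        a = simulate_step(
            step_config.replace(stimulus=StepStimulus(0.2, 0.6, 0.01), solver=sol)
        )
        b = simulate_step(
            step_config.replace(stimulus=StepStimulus(0.2, 1.8, 0.01), solver=sol)
        )
        same_fold = simulate_step(
            step_config.replace(stimulus=StepStimulus(0.4, 1.2, 0.01), solver=sol)
        )
        assert fcd_distance(a, b, 0.01, 0.01) > 10 * fcd_distance(a, same_fold, 0.01, 0.01)


class TestAdaptationTimeTrends:
    def test_monotone_in_step_size(self):
        sol = SolverSettings(dt=2e-6, t_end=0.6)
        pos, neg = [], []
        for c in [0.1, 1.0, 5.0]:
            up = SimulationConfig(stimulus=StepStimulus(0.0, c, 0.01), solver=sol)
            dn = SimulationConfig(stimulus=StepStimulus(c, 0.0, 0.01), solver=sol)
            pos.append(adaptation_time(simulate_step(up), 0.01))
            neg.append(adaptation_time(simulate_step(dn), 0.01))
        assert pos[0] > pos[1] > pos[2]  # faster for larger positive steps
        assert neg[0] < neg[1] < neg[2]  # slower for larger negative steps


class TestDetailedBalance:
    def test_constant_stimulus_always_balanced(self, step_config):
        cfg = step_config.replace(stimulus=StepStimulus(1.0, 1.0, 0.05))
        assert detailed_balance_report(simulate_step(cfg)).all()

    def test_transient_breaks_and_restores_balance(self, step_config):
        traj = simulate_step(step_config)
        rep = detailed_balance_report(traj)
        i0 = np.searchsorted(traj.t, 0.05)
        assert rep[: i0 - 1].all()  # equilibrated before the step
        assert not rep[i0]  # broken right after the increase
        assert rep[-1]  # equilibrated again when adapted
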