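"""Unit and property tests for the discrete LIF model family."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mapsnn import (
    NeuronParams, SimulationConfig, decay_factor, event_driven_oracle,
    hard_reset_step, normalize_input, run_discrete_model,
    simplified_numerical_step, soft_reset_step, standard_numerical_step,
)

T_OMEGA = 4.0 * math.log(2.0)   # inter-spike interval at tau=4, R*I=2, v_th=1


class TestDecayAndInput:
    def test_decay_factor_value(self):
        assert decay_factor(4.0, 4.0) == pytest.approx(math.exp(-1.0))

    def test_decay_factor_limits(self):
        assert decay_factor(1e-9, 4.0) == pytest.approx(1.0)
        assert decay_factor(1e9, 4.0) == pytest.approx(0.0, abs=1e-300)

    @pytest.mark.parametrize("dt,tau", [(0, 4), (-1, 4), (4, 0), (4, -2)])
    def test_decay_factor_rejects_nonpositive(self, dt, tau):
        with pytest.raises(ValueError):
            decay_factor(dt, tau)

    def test_normalized_input_zero_current(self, params_tau4_r2):
        assert normalize_input(0.0, 5.0, params_tau4_r2) == 0.0

    def test_normalized_input_value(self, params_tau4_r2):
        # (1 - e^-2.5) * 2 for I=1, R=2, dt=10, tau=4
        got = normalize_input(1.0, 10.0, params_tau4_r2)
        assert got == pytest.approx((1 - math.exp(-2.5)) * 2.0)

    def test_normalized_input_steady_state(self, params_tau4_r2):
        # dt >> tau approaches the asymptote R*I
        assert normalize_input(1.5, 1e4, params_tau4_r2) == pytest.approx(3.0)


class TestBinarySteps:
    P = NeuronParams(tau=1.0, R=2.0, v_th=1.0)
    DT = -math.log(0.2)   # decay factor exactly 0.2

    def test_hard_reset_discards_excess(self):
        v, s = hard_reset_step(1.5, 1, 0.5, self.P, self.DT)
        assert v == pytest.approx(0.5)
        assert s == 0

    def test_soft_reset_keeps_scaled_excess(self):
        v, s = soft_reset_step(1.5, 1, 0.5, self.P, self.DT)
        assert v == pytest.approx(0.6)
        assert s == 0

    def test_quiescent(self):
        assert hard_reset_step(0.0, 0, 0.0, self.P, self.DT) == (0.0, 0)

    def test_suprathreshold_fires(self):
        v, s = hard_reset_step(0.0, 0, 2.0, self.P, self.DT)
        assert (v, s) == (2.0, 1)

    def test_models_coincide_at_zero_excess(self):
        # previous spike at exactly v_th: no excess, identical updates
        vh, sh = hard_reset_step(1.0, 1, 0.3, self.P, self.DT)
        vs, ss = soft_reset_step(1.0, 1, 0.3, self.P, self.DT)
        assert vh == pytest.approx(vs)
        assert sh == ss

    def test_subthreshold_trajectories_identical(self, params_tau4_r2):
        # while nothing fires, soft and hard reset are the same recursion
        i_norm = normalize_input(0.4, 1.0, params_tau4_r2)  # drive 0.8 < v_th
        vh = vs = 0.0
        for _ in range(50):
            vh, sh = hard_reset_step(vh, 0, i_norm, params_tau4_r2, 1.0)
            vs, ss = soft_reset_step(vs, 0, i_norm, params_tau4_r2, 1.0)
            assert sh == ss == 0
            assert vh == pytest.approx(vs)


class TestStandardStep:
    def test_closed_form_example(self, params_tau4_r2):
        out = standard_numerical_step(0.0, 1.0, 10.0, params_tau4_r2)
        assert out.n_spikes == 3
        assert out.t_alpha == pytest.approx(T_OMEGA)
        assert out.t_omega == pytest.approx(T_OMEGA)
        assert out.t_r == pytest.approx(10.0 - 3 * T_OMEGA)
        assert out.v_residual == pytest.approx(
            (1 - math.exp(-(10.0 - 3 * T_OMEGA) / 4.0)) * 2.0)

    @pytest.mark.parametrize("dt", [0.5, 5.0, 50.0, 500.0])
    def test_subthreshold_drive_never_fires(self, dt):
        p = NeuronParams(tau=4.0, R=2.0, v_th=1.0)
        out = standard_numerical_step(0.0, 0.4, dt, p)   # R*I = 0.8 < v_th
        assert out.n_spikes == 0
        # approaches the asymptote R*I from below (equality at fp precision)
        assert out.v_residual <= 0.8

    def test_boundary_spike_at_window_end(self, params_tau4_r2):
        # dt = tau ln 2 makes V_e hit v_th exactly: one spike, zero residual
        dt = 4.0 * math.log(2.0)
        out = standard_numerical_step(0.0, 1.0, dt, params_tau4_r2)
        assert out.n_spikes == 1
        assert out.t_alpha == pytest.approx(dt)
        assert out.t_r == pytest.approx(0.0, abs=1e-9)
        assert out.v_residual == pytest.approx(0.0, abs=1e-9)

    def test_rejects_start_at_threshold(self, params_tau4_r2):
        with pytest.raises(ValueError):
            standard_numerical_step(1.0, 1.0, 1.0, params_tau4_r2)

    @given(v0=st.floats(0.0, 0.999), Ic=st.floats(0.05, 5.0),
           dt=st.floats(0.01, 100.0))
    def test_residual_legality(self, v0, Ic, dt):
        p = NeuronParams(tau=4.0, R=2.0, v_th=1.0)
        for step in (standard_numerical_step, simplified_numerical_step):
            out = step(v0, Ic, dt, p)
            assert 0.0 <= out.v_residual < p.v_th
            if out.n_spikes == 0:
                assert out.v_residual == out.v_estimate


class TestSimplifiedStep:
    def test_tracks_standard_when_drive_large(self):
        # v_th/(R*I) = 0.05: counts agree within one spike
        p = NeuronParams(tau=4.0, R=20.0, v_th=1.0)
        for dt in (0.5, 1.0, 2.0):
            n_std = standard_numerical_step(0.0, 1.0, dt, p).n_spikes
            n_sim = simplified_numerical_step(0.0, 1.0, dt, p).n_spikes
            assert abs(n_sim - n_std) <= 1

    def test_subthreshold(self):
        p = NeuronParams(tau=4.0, R=2.0, v_th=1.0)
        assert simplified_numerical_step(0.0, 0.4, 7.0, p).n_spikes == 0

    def test_floor_just_below_one(self):
        # v0 = 0.999 v_th, tiny dt, huge drive: count floors to zero
        p = NeuronParams(tau=4.0, R=1000.0, v_th=1.0)
        out = simplified_numerical_step(0.999, 1.0, 1e-6, p)
        assert out.n_spikes == 0


class TestEventDrivenOracle:
    def test_reference_count(self, params_tau4_r2, cfg_1s):
        times = event_driven_oracle(cfg_1s(1.0), params_tau4_r2)
        assert len(times) == 360
        assert times[0] == pytest.approx(T_OMEGA)
        assert np.allclose(np.diff(times), T_OMEGA)

    def test_drive_exactly_threshold_never_fires(self, cfg_1s):
        p = NeuronParams(tau=4.0, R=1.0, v_th=1.0)   # R*I = v_th
        assert len(event_driven_oracle(cfg_1s(1.0), p)) == 0

    def test_run_shorter_than_first_spike(self, params_tau4_r2):
        cfg = SimulationConfig(current=1.0, total_time=2.0, dt=1.0)
        assert len(event_driven_oracle(cfg, params_tau4_r2)) == 0


class TestRunDiscreteModel:
    @pytest.mark.parametrize("dt", [0.5, 1.0, 2.0, 4.0, 5.0, 10.0, 20.0, 25.0, 50.0])
    def test_standard_count_independent_of_partition(self, dt, params_tau4_r2,
                                                     cfg_1s):
        run = run_discrete_model("standard", cfg_1s(dt), params_tau4_r2)
        assert run.total_spikes() == 360

    def test_soft_reset_one_spike_per_window_under_strong_drive(
            self, params_tau4_r2, cfg_1s):
        # dt = 10 > t_omega: every window stays suprathreshold
        run = run_discrete_model("soft_reset", cfg_1s(10.0), params_tau4_r2)
        assert run.total_spikes() == 100
        assert np.all(run.counts == 1)

    def test_zero_current_silent(self, params_tau4_r2, cfg_1s):
        run = run_discrete_model("standard", cfg_1s(10.0, I=0.0), params_tau4_r2)
        assert run.total_spikes() == 0
        assert np.all(run.grid.counts == 0)

    def test_unknown_model_rejected(self, params_tau4_r2, cfg_1s):
        with pytest.raises(ValueError, match="unknown model"):
            run_discrete_model("izhikevich", cfg_1s(1.0), params_tau4_r2)

    def test_partial_final_window_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            SimulationConfig(current=1.0, total_time=1000.0, dt=3.0)

    @given(tau=st.sampled_from([2.0, 4.0, 8.0, 40.0]),
           R=st.sampled_from([2.0, 5.0, 20.0]),
           dt=st.sampled_from([0.5, 1.0, 2.0, 5.0, 10.0, 25.0]))
    def test_dt_invariance_matches_oracle(self, tau, R, dt):
        p = NeuronParams(tau=tau, R=R, v_th=1.0)
        cfg = SimulationConfig(current=1.0, total_time=1000.0, dt=dt)
        n_oracle = len(event_driven_oracle(cfg, p))
        n_run = run_discrete_model("standard", cfg, p).total_spikes()
        assert abs(n_run - n_oracle) <= 1
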