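"""Closed-loop forward simulation: determinism, reductions, RMSE, assistance."""

import numpy as np
import pytest

from ankleflex.geometry import ankle_moment
from ankleflex.muscle import E_MIN, _equilibrium, activation_step, init_fiber_length
from ankleflex.reflex import (
    DelayLine,
    ReflexGains,
    soleus_excitation,
    stance_gate,
    tibialis_excitation,
)
from ankleflex.simulate import (
    AnkleModel,
    GaitTrial,
    exo_assist,
    moment_rmse,
    simulate_trial,
)
from ankleflex.synthetic import GeneratorConfig, make_perturbed_cycle, make_steady_cycle


def short_trial(n=500, dt=0.001, dcom_amp=0.0, mass=70.0):
    t = np.arange(n) * dt
    q = 0.1 * np.sin(2 * np.pi * t / (n * dt))
    fz = mass * 9.81 * np.clip(np.sin(2 * np.pi * t / (n * dt)), 0, None)
    dcom = dcom_amp * np.sin(2 * np.pi * t / (n * dt))
    return GaitTrial(time=t, q=q, fz=fz, dcom=dcom, mass=mass)


GAINS = ReflexGains(G_sol=1.8e-4, K_sol=0.4, e_ta_0=0.01, G_ta=11.0, lm_off=0.07,
                    G_sol_ta=-1e-4, K_ta=-0.2)


class TestSimulation:
    def test_bit_identical_determinism(self, model):
        trial = short_trial(dcom_amp=0.1)
        r1 = simulate_trial(trial, GAINS, model)
        r2 = simulate_trial(trial, GAINS, model)
        np.testing.assert_array_equal(r1.moment, r2.moment)
        np.testing.assert_array_equal(r1.lm_ta, r2.lm_ta)

    def test_zero_deviation_channel_neutralizes_com_gains(self, model):
        """dCOM = 0 with nonzero COM gains matches the zero-gain run exactly."""
        trial = short_trial(dcom_amp=0.0)
        with_k = simulate_trial(trial, GAINS, model)
        without_k = simulate_trial(trial, GAINS.without_com_feedback(), model)
        np.testing.assert_array_equal(with_k.moment, without_k.moment)

    def test_matches_pure_python_rollout(self, model):
        """The compiled kernel reproduces a step-by-step rollout built from the
        public muscle/reflex operations."""
        trial = short_trial(n=400, dcom_amp=0.15)
        res = simulate_trial(trial, GAINS, model)

        dt = trial.dt
        d_m = round(GAINS.tau_m / dt)
        d_com = round(GAINS.tau_com / dt)
        pf, ta, geom = model.plantarflexor, model.dorsiflexor, model.geometry
        a_s = float(np.clip(GAINS.e_sol_0, E_MIN, 1.0))
        a_t = float(np.clip(GAINS.e_ta_0, E_MIN, 1.0))
        lm_s = init_fiber_length(a_s, float(geom.mtu_length(trial.q[0], "pf")), pf)
        lm_t = init_fiber_length(a_t, float(geom.mtu_length(trial.q[0], "df")), ta)
        f0, _ = _equilibrium(a_s, lm_s, float(geom.mtu_length(trial.q[0], "pf")), pf)
        f_line = DelayLine(d_m, fill=f0)
        l_line = DelayLine(d_m, fill=lm_t)
        moments = np.empty(trial.n)
        for i in range(trial.n):
            gate = float(stance_gate(trial.fz[i], trial.mass))
            f_del = f_line.read(i)
            l_del = l_line.read(i)
            c_del = trial.dcom[i - d_com] if i >= d_com else trial.dcom[0]
            es = float(soleus_excitation(f_del, c_del, gate, GAINS))
            et = float(tibialis_excitation(l_del, f_del, c_del, gate, GAINS))
            lmt_s = float(geom.mtu_length(trial.q[i], "pf"))
            lmt_t = float(geom.mtu_length(trial.q[i], "df"))
            F_s, v_s = _equilibrium(a_s, lm_s, lmt_s, pf)
            F_t, v_t = _equilibrium(a_t, lm_t, lmt_t, ta)
            f_line.write(F_s)
            l_line.write(lm_t)
            moments[i] = float(ankle_moment(trial.q[i], F_s, F_t, geom))
            a_s = activation_step(es, a_s, dt, pf)
            a_t = activation_step(et, a_t, dt, ta)
            lm_s += dt * v_s
            lm_t += dt * v_t
        np.testing.assert_allclose(res.moment, moments, rtol=1e-9, atol=1e-9)

    def test_swing_settles_to_static_baseline_moment(self, model):
        """Constant swing input (F_z = 0): the moment stays at the static
        moment of the baseline excitations, computed by an independent
        equilibrium solve."""
        n = 3000
        t = np.arange(n) * 0.001
        trial = GaitTrial(
            time=t, q=np.full(n, 0.05), fz=np.zeros(n), dcom=np.zeros(n)
        )
        gains = ReflexGains()  # all feedback gains zero
        res = simulate_trial(trial, gains, model)
        # oracle: static equilibrium at the baseline activations
        geom = model.geometry
        a_s, a_t = gains.e_sol_0, float(np.clip(gains.e_ta_0, E_MIN, 1.0))
        lm_s = init_fiber_length(a_s, float(geom.mtu_length(0.05, "pf")), model.plantarflexor)
        lm_t = init_fiber_length(a_t, float(geom.mtu_length(0.05, "df")), model.dorsiflexor)
        F_s, _ = _equilibrium(a_s, lm_s, float(geom.mtu_length(0.05, "pf")), model.plantarflexor)
        F_t, _ = _equilibrium(a_t, lm_t, float(geom.mtu_length(0.05, "df")), model.dorsiflexor)
        static = float(ankle_moment(0.05, F_s, F_t, geom))
        assert res.moment[-1] == pytest.approx(static, rel=1e-3)
        assert np.ptp(res.moment[-1000:]) < 1e-3 * max(abs(static), 1.0)

    def test_push_increases_moment_with_positive_com_gain(self, gen_cfg):
        """A forward push with K_sol > 0 raises the stance plantarflexion
        moment relative to the no-COM-feedback run."""
        push = make_perturbed_cycle(gen_cfg, "push", 0.12)
        with_com = simulate_trial(push, gen_cfg.true_gains, gen_cfg.model, True)
        without = simulate_trial(push, gen_cfg.true_gains, gen_cfg.model, False)
        onset = int(gen_cfg.onset_phase * push.n)
        stance = (with_com.gate > 0.5) & (np.arange(push.n) > onset)
        assert with_com.moment[stance].mean() > without.moment[stance].mean()

    def test_delay_not_multiple_of_dt_raises(self, model):
        trial = short_trial(n=200, dt=0.0007)
        with pytest.raises(ValueError, match="not an integer multiple"):
            simulate_trial(trial, GAINS, model)

    def test_non_finite_channel_rejected(self, model):
        trial = short_trial(n=100)
        trial.q[50] = np.nan
        with pytest.raises(ValueError, match="finite"):
            simulate_trial(trial, GAINS, model)


class TestMomentRmse:
    def test_zero_when_equal(self, model):
        trial = short_trial(n=300)
        sim = simulate_trial(trial, GAINS, model)
        trial.moment = sim.moment.copy()
        assert moment_rmse(sim, trial) == 0.0

    def test_constant_offset_without_scaling(self, model):
        trial = short_trial(n=300)
        sim = simulate_trial(trial, GAINS, model)
        trial.moment = sim.moment + 2.0
        assert moment_rmse(sim, trial, scale_to_reference=False) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_pair(self, model, rng):
        trial = short_trial(n=300)
        sim = simulate_trial(trial, GAINS, model)
        trial.moment = sim.moment + rng.normal(0, 3.0, trial.n)
        expected = np.sqrt(np.mean((sim.moment - trial.moment) ** 2))
        assert moment_rmse(sim, trial, scale_to_reference=False) == pytest.approx(expected)

    def test_reference_subject_scaling(self, model):
        base = short_trial(n=300, mass=80.0)
        trial = GaitTrial(time=base.time, q=base.q, fz=base.fz, dcom=base.dcom,
                          mass=80.0, height=1.80)
        sim = simulate_trial(trial, GAINS, model)
        trial.moment = sim.moment + 1.0
        s = (70.0 * 1.75) / (80.0 * 1.80)
        assert moment_rmse(sim, trial) == pytest.approx(s * 1.0)

    def test_missing_target_raises(self, model):
        trial = short_trial(n=100)
        sim = simulate_trial(trial, GAINS, model)
        with pytest.raises(ValueError, match="no target moment"):
            moment_rmse(sim, trial)


class TestExoAssist:
    @pytest.mark.parametrize(
        "moment, fraction, expected",
        [(100.0, 0.3, 30.0), (100.0, 0.0, 0.0), (-40.0, 0.3, -12.0)],
    )
    def test_fraction_of_moment(self, moment, fraction, expected):
        assert exo_assist(moment, fraction) == pytest.approx(expected)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            exo_assist(10.0, 1.5)


class TestStepSizeConvergence:
    def test_halving_dt_changes_moment_below_one_percent(self):
        cfg = GeneratorConfig(seed=1)
        coarse = make_steady_cycle(cfg)
        fine = make_steady_cycle(cfg.replace(dt=0.0005))
        m_fine = np.interp(coarse.time, fine.time, fine.moment)
        rel = np.sqrt(np.mean((coarse.moment - m_fine) ** 2)) / np.sqrt(
            np.mean(coarse.moment**2)
        )
        assert rel < 0.01
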