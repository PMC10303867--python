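"""JIT-compiled inner loop of the closed-loop forward simulation.

The reflex controller feeds back the simulation's own delayed plantarflexor
force and dorsiflexor fiber length, so the rollout is inherently sequential;
this module compiles the per-step update with numba.  The formulas mirror
:mod:`ankleflex.muscle`, :mod:`ankleflex.geometry` and :mod:`ankleflex.reflex`
exactly (a cross-check test asserts agreement with the pure-Python path).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# constants duplicated from muscle.py (numba cannot close over the module)
_KT, _TC1, _TC2, _TC3 = 35.0, 0.200, 0.995, 0.250
_KPE, _E0 = 4.0, 0.6
_D1, _D2, _D3, _D4 = -0.318, -8.149, -0.374, 0.886
_E_MIN = 1e-3
_G = 9.81


@njit(cache=True)
def _active_fl(lm):
    f = 0.815 * np.exp(-0.5 * (lm - 1.055) ** 2 / (0.162 + 0.0633 * lm) ** 2)
    f += 0.433 * np.exp(-0.5 * (lm - 0.717) ** 2 / (-0.0299 + 0.200 * lm) ** 2)
    f += 0.100 * np.exp(-0.5 * (lm - 1.000) ** 2 / 0.354**2)
    return f


@njit(cache=True)
def _passive_fl(lm):
    return (np.exp(_KPE * (lm - 1.0) / _E0) - 1.0) / (np.exp(_KPE) - 1.0)


_SLACK_EPS = 1e-3
_TAU_BLEND = 50.0


@njit(cache=True)
def _tendon_fl(ltn):
    f = _TC1 * np.exp(_KT * (ltn - _TC2)) - _TC3
    return 0.5 * (f + np.sqrt(f * f + _SLACK_EPS**2))


@njit(cache=True)
def _fv_value_slope(vn):
    t = _D2 * vn + _D3
    s = np.sqrt(t * t + 1.0)
    return _D1 * np.log(t + s) + _D4, _D1 * _D2 / s


@njit(cache=True)
def _solve_fiber_velocity(afl, target, damping):
    f_lo, _ = _fv_value_slope(-1.0)
    f_hi, _ = _fv_value_slope(1.0)
    if afl * f_lo - damping >= target:
        return -1.0
    if afl * f_hi + damping <= target:
        return 1.0
    v = 0.0
    for _ in range(50):
        fv, dfv = _fv_value_slope(v)
        g = afl * fv + damping * v - target
        step = g / (afl * dfv + damping)
        v = v - step
        if v < -1.0:
            v = -1.0
        elif v > 1.0:
            v = 1.0
        if abs(step) < 1e-12:
            break
    return v


@njit(cache=True)
def _equilibrium(a, lm, lmt, f_max, l_opt, l_ts, v_max, alpha_opt, damping):
    """Tendon force [N] and fiber velocity [m/s]; mirrors muscle._equilibrium."""
    if alpha_opt > 0.0:
        s = l_opt * np.sin(alpha_opt) / lm
        if s > 0.99:
            s = 0.99
        cosa = np.sqrt(1.0 - s * s)
    else:
        cosa = 1.0
    ltn = (lmt - lm * cosa) / l_ts
    ftn = _tendon_fl(ltn)
    lmn = lm / l_opt
    f_pas = _passive_fl(lmn)
    afl = a * _active_fl(lmn)
    vn = _solve_fiber_velocity(afl, ftn / cosa - f_pas, damping)
    return ftn * f_max, vn * v_max * l_opt


@njit(cache=True)
def _act_step(e, a, dt, tau_act, tau_deact):
    if e < _E_MIN:
        e = _E_MIN
    elif e > 1.0:
        e = 1.0
    w = 0.5 + 0.5 * np.tanh(_TAU_BLEND * (e - a))
    inv_tau = w / tau_act + (1.0 - w) / tau_deact
    an = a + dt * (e - a) * inv_tau
    if an < 0.0:
        an = 0.0
    elif an > 1.0:
        an = 1.0
    return an


@njit(cache=True)
def _polyval(c, x):
    y = 0.0
    for k in range(c.shape[0] - 1, -1, -1):
        y = y * x + c[k]
    return y


@njit(cache=True)
def _polyder_val(c, x):
    y = 0.0
    for k in range(c.shape[0] - 1, 0, -1):
        y = y * x + k * c[k]
    return y


@njit(cache=True)
def simulate_kernel(
    q,
    fz,
    dcom,
    dt,
    mass,
    pf,  # (f_max, l_m_opt, l_t_slack, v_m_max, alpha_opt, tau_act, tau_deact)
    ta,
    c_pf,  # ascending polynomial coefficients, lmt(q)
    c_ta,
    g,  # (e_sol_0, G_sol, K_sol, e_ta_0, G_ta, lm_off, G_sol_ta, K_ta)
    d_m,  # local reflex delay [samples]
    d_com,  # COM feedback delay [samples]
    a_pf0,
    lm_pf0,
    a_ta0,
    lm_ta0,
    use_com,
):
    n = q.shape[0]
    e_sol = np.empty(n)
    e_ta = np.empty(n)
    a_sol = np.empty(n)
    a_ta = np.empty(n)
    lm_sol = np.empty(n)
    lm_ta = np.empty(n)
    f_sol = np.empty(n)
    f_ta = np.empty(n)
    mom = np.empty(n)
    gate = np.empty(n)

    a1, l1 = a_pf0, lm_pf0
    a2, l2 = a_ta0, lm_ta0
    mg = mass * _G

    # delay-line fill values: steady-state hold of the initial sample
    lmt1_0 = _polyval(c_pf, q[0])
    f_sol_fill, _ = _equilibrium(a1, l1, lmt1_0, pf[0], pf[1], pf[2], pf[3], pf[4], pf[7])
    lm_ta_fill = lm_ta0
    dcom_fill = dcom[0]

    for i in range(n):
        qi = q[i]
        lmt1 = _polyval(c_pf, qi)
        lmt2 = _polyval(c_ta, qi)
        k_fz = 0.5 * np.tanh(10.0 * (fz[i] / mg - 0.4)) + 0.5
        gate[i] = k_fz

        f_del = f_sol[i - d_m] if i >= d_m else f_sol_fill
        l_del = lm_ta[i - d_m] if i >= d_m else lm_ta_fill
        c_del = dcom[i - d_com] if i >= d_com else dcom_fill

        es = g[0] + k_fz * g[1] * f_del
        et = g[3] + g[4] * (l_del - g[5]) + k_fz * g[6] * f_del
        if use_com:
            es += k_fz * g[2] * c_del
            et += k_fz * g[7] * c_del
        if es < _E_MIN:
            es = _E_MIN
        elif es > 1.0:
            es = 1.0
        if et < _E_MIN:
            et = _E_MIN
        elif et > 1.0:
            et = 1.0

        F1, v1 = _equilibrium(a1, l1, lmt1, pf[0], pf[1], pf[2], pf[3], pf[4], pf[7])
        F2, v2 = _equilibrium(a2, l2, lmt2, ta[0], ta[1], ta[2], ta[3], ta[4], ta[7])

        e_sol[i] = es
        e_ta[i] = et
        a_sol[i] = a1
        a_ta[i] = a2
        lm_sol[i] = l1
        lm_ta[i] = l2
        f_sol[i] = F1
        f_ta[i] = F2
        mom[i] = -_polyder_val(c_pf, qi) * F1 - _polyder_val(c_ta, qi) * F2

        a1 = _act_step(es, a1, dt, pf[5], pf[6])
        a2 = _act_step(et, a2, dt, ta[5], ta[6])
        l1 = l1 + dt * v1
        l2 = l2 + dt * v2

    return e_sol, e_ta, a_sol, a_ta, lm_sol, lm_ta, f_sol, f_ta, mom, gate
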