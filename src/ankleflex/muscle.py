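"""Hill-type muscle-tendon unit.

Each virtual muscle consists of first-order activation dynamics, an elastic
series tendon, a parallel passive element and a contractile element with
active force-length and force-velocity relationships.  The dimensionless
characteristic curves follow the smooth parameterization of De Groote et al.
(2016, Ann Biomed Eng 44:2922-2936), which is continuously differentiable and
therefore well suited to gradient-based parameter identification.

State choice: the muscle state is (activation, fiber length).  At every step
the series-tendon force is computed from the tendon stretch, the force
equilibrium along the tendon

    F_t(l_t) = f_max * (a * f_act(l_m~) * f_v(v_m~) + f_pas(l_m~)) * cos(alpha)

is inverted analytically for the normalized fiber velocity (the force-velocity
curve has a closed-form inverse), and the fiber length is advanced with
forward Euler.  This avoids an iterative equilibrium solve inside the
integration loop; the equilibrium residual is zero by construction at every
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MuscleTendonParams",
    "MuscleState",
    "activation_step",
    "muscle_dynamics_step",
    "init_fiber_length",
    "tendon_force_length",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "force_velocity_inverse",
    "pennation_cosine",
    "E_MIN",
    "GRAVITY",
]

# Excitation floor shared with the reflex laws: excitations are clamped to
# [E_MIN, 1] before the activation dynamics to avoid degenerate zero-activation
# dynamics.
E_MIN = 1e-3

GRAVITY = 9.81  # m/s^2

# --- dimensionless curve constants (De Groote et al. 2016) -------------------
# tendon force-length  f_t(lt~) = c1*exp(kT*(lt~ - c2)) - c3, floored at 0
_KT, _TC1, _TC2, _TC3 = 35.0, 0.200, 0.995, 0.250
# active force-length: sum of three Gaussians, rows (b1, b2, b3, b4)
_FL = (
    (0.815, 1.055, 0.162, 0.0633),
    (0.433, 0.717, -0.0299, 0.200),
    (0.100, 1.000, 0.354, 0.000),
)
# passive force-length
_KPE, _E0 = 4.0, 0.6
# force-velocity  f_v(v~) = d1*log(d2*v~ + d3 + sqrt((d2*v~ + d3)^2 + 1)) + d4
_D1, _D2, _D3, _D4 = -0.318, -8.149, -0.374, 0.886


@dataclass(frozen=True)
class MuscleTendonParams:
    """Mechanical constants of one muscle-tendon unit.

    Parameters
    ----------
    f_max : float
        Maximal isometric fiber force [N].
    l_m_opt : float
        Optimal fiber length [m].
    l_t_slack : float
        Tendon slack length [m].
    v_m_max : float
        Maximal contraction velocity [optimal fiber lengths / s].
    alpha_opt : float
        Pennation angle at optimal fiber length [rad].  A constant
        muscle-thickness model is used: l_m*sin(alpha) = l_m_opt*sin(alpha_opt).
    tau_act, tau_deact : float
        Activation / deactivation time constants [s].
    damping : float
        Normalized parallel fiber damping.  The fiber velocity is obtained
        from the damped force equilibrium
        ``a*f_act(lm~)*f_v(vm~) + f_pas(lm~) + damping*vm~ = F_t/(f_max*cos(alpha))``,
        which keeps the fiber dynamics well-posed and non-stiff at low
        activation (an undamped inversion of the force-velocity curve has a
        slope ~ 1/(a*f_act) there, which destabilizes an explicit integrator
        on a slack tendon).
    """

    f_max: float
    l_m_opt: float
    l_t_slack: float
    v_m_max: float = 10.0
    alpha_opt: float = 0.0
    tau_act: float = 0.015
    tau_deact: float = 0.060
    damping: float = 0.1

    def __post_init__(self) -> None:
        for name in ("f_max", "l_m_opt", "l_t_slack", "v_m_max", "tau_act", "tau_deact"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (np.isfinite(self.alpha_opt) and self.alpha_opt >= 0):
            raise ValueError(f"alpha_opt must be >= 0, got {self.alpha_opt!r}")
        if self.tau_deact < self.tau_act:
            raise ValueError("tau_deact must be >= tau_act")
        if not (np.isfinite(self.damping) and self.damping >= 0):
            raise ValueError("damping must be >= 0")

    def replace(self, **kw) -> "MuscleTendonParams":
        return replace(self, **kw)


@dataclass
class MuscleState:
    """Activation and fiber length, with the last computed tendon force."""

    a: float
    l_m: float
    F_t: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError(f"activation out of [0, 1]: {self.a!r}")
        if not self.l_m > 0:
            raise ValueError(f"fiber length must be > 0: {self.l_m!r}")


# --- characteristic curves ---------------------------------------------------

# smoothing constants: tendon-slack floor width (normalized force) and the
# steepness of the activation/deactivation time-constant blend.  Both keep the
# rollout continuously differentiable, which the finite-difference gradients of
# the identification require; at the stated example inputs they are inactive to
# machine precision.
_SLACK_EPS = 1e-3
_TAU_BLEND = 50.0


def tendon_force_length(lt_norm):
    """Normalized tendon force vs. tendon length / slack length (>= 0).

    The exponential characteristic is floored at zero with a smooth hinge of
    width ``_SLACK_EPS`` so that going slack does not introduce a derivative
    discontinuity.
    """
    f = _TC1 * np.exp(_KT * (np.asarray(lt_norm, dtype=float) - _TC2)) - _TC3
    return 0.5 * (f + np.sqrt(f * f + _SLACK_EPS**2))


def active_force_length(lm_norm):
    """Active force-length multiplier (max ~1 at optimal fiber length)."""
    lm = np.asarray(lm_norm, dtype=float)
    f = np.zeros_like(lm)
    for b1, b2, b3, b4 in _FL:
        w = b3 + b4 * lm
        f = f + b1 * np.exp(-0.5 * (lm - b2) ** 2 / (w * w))
    return f


def passive_force_length(lm_norm):
    """Passive parallel-element force vs. normalized fiber length."""
    lm = np.asarray(lm_norm, dtype=float)
    return (np.exp(_KPE * (lm - 1.0) / _E0) - 1.0) / (math.exp(_KPE) - 1.0)


def force_velocity(v_norm):
    """Force-velocity multiplier (<= 1 shortening, > 1 lengthening)."""
    v = np.asarray(v_norm, dtype=float)
    t = _D2 * v + _D3
    return _D1 * np.log(t + np.sqrt(t * t + 1.0)) + _D4


def force_velocity_inverse(fv):
    """Closed-form inverse of :func:`force_velocity`."""
    f = np.asarray(fv, dtype=float)
    return (np.sinh((f - _D4) / _D1) - _D3) / _D2


def pennation_cosine(l_m: float, params: MuscleTendonParams) -> float:
    """cos(pennation) under the constant-thickness model."""
    h = params.l_m_opt * math.sin(params.alpha_opt)
    if h == 0.0:
        return 1.0
    s = min(h / l_m, 0.99)
    return math.sqrt(1.0 - s * s)


# --- dynamics ----------------------------------------------------------------

def activation_step(e: float, a: float, dt: float, params: MuscleTendonParams) -> float:
    """One forward-Euler step of the first-order activation dynamics.

    The time constant is ``tau_act`` when the (clamped) excitation exceeds the
    activation and ``tau_deact`` otherwise; the two regimes are blended with a
    steep tanh of the excitation-activation difference so the dynamics stay
    smooth, and the result is clamped to [0, 1].
    """
    if not (np.isfinite(e) and np.isfinite(a) and np.isfinite(dt)):
        raise ValueError("non-finite excitation, activation or dt")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt!r}")
    e = min(max(e, E_MIN), 1.0)
    w = 0.5 + 0.5 * math.tanh(_TAU_BLEND * (e - a))
    inv_tau = w / params.tau_act + (1.0 - w) / params.tau_deact
    a_new = a + dt * (e - a) * inv_tau
    return min(max(a_new, 0.0), 1.0)


def _fv_value_slope(v_norm: float):
    t = _D2 * v_norm + _D3
    s = math.sqrt(t * t + 1.0)
    return _D1 * math.log(t + s) + _D4, _D1 * _D2 / s


def solve_fiber_velocity(afl: float, target: float, damping: float) -> float:
    """Normalized fiber velocity from the damped force equilibrium.

    Solves ``afl * f_v(v~) + damping * v~ = target`` for ``v~`` in [-1, 1]
    (Newton on a strictly increasing function; endpoints saturate).
    """
    f_lo, _ = _fv_value_slope(-1.0)
    f_hi, _ = _fv_value_slope(1.0)
    if afl * f_lo + damping * (-1.0) >= target:
        return -1.0
    if afl * f_hi + damping * 1.0 <= target:
        return 1.0
    v = 0.0
    for _ in range(50):
        fv, dfv = _fv_value_slope(v)
        g = afl * fv + damping * v - target
        step = g / (afl * dfv + damping)
        v = min(max(v - step, -1.0), 1.0)
        if abs(step) < 1e-12:
            break
    return v


def _equilibrium(a: float, l_m: float, lmt: float, params: MuscleTendonParams):
    """Tendon force [N] and fiber velocity [m/s] from the damped equilibrium."""
    cosa = pennation_cosine(l_m, params)
    lt_norm = (lmt - l_m * cosa) / params.l_t_slack
    ft_norm = float(tendon_force_length(lt_norm))
    lm_norm = l_m / params.l_m_opt
    f_pas = float(passive_force_length(lm_norm))
    afl = a * float(active_force_length(lm_norm))
    target = ft_norm / cosa - f_pas
    v_norm = solve_fiber_velocity(afl, target, params.damping)
    return ft_norm * params.f_max, v_norm * params.v_m_max * params.l_m_opt


def muscle_dynamics_step(
    state: MuscleState,
    e: float,
    lmt: float,
    vmt: float,
    dt: float,
    params: MuscleTendonParams,
):
    """Advance one muscle by one Euler step; returns ``(new_state, F_t)``.

    ``vmt`` (musculotendon velocity) is part of the step interface but does not
    enter the update: with a fiber-length state the fiber velocity is obtained
    from the force equilibrium and the musculotendon velocity acts only through
    the sequence of ``lmt`` values supplied to successive calls.
    """
    if not all(np.isfinite(x) for x in (e, lmt, vmt, dt)):
        raise ValueError("non-finite input to muscle_dynamics_step")
    F_t, v_m = _equilibrium(state.a, state.l_m, lmt, params)
    a_new = activation_step(e, state.a, dt, params)
    l_m_new = state.l_m + dt * v_m
    if not (np.isfinite(l_m_new) and l_m_new > 0):
        raise RuntimeError(f"fiber length became non-physical ({l_m_new!r})")
    return MuscleState(a=a_new, l_m=l_m_new, F_t=F_t), F_t


_FV0 = float(force_velocity(0.0))  # isometric force-velocity value (~1.002)


def init_fiber_length(
    a: float, lmt: float, params: MuscleTendonParams, tol: float = 1e-12
) -> float:
    """Fiber length solving the static (isometric) force equilibrium.

    Used to initialize simulations without start-up transients.  Raises
    ``RuntimeError`` when the equilibrium cannot be bracketed within the
    physiological fiber-length range [0.2, 2.0] x optimal fiber length.
    """

    def residual(l_m: float) -> float:
        cosa = pennation_cosine(l_m, params)
        lt_norm = (lmt - l_m * cosa) / params.l_t_slack
        ft = float(tendon_force_length(lt_norm))
        lm_norm = l_m / params.l_m_opt
        fiber = (
            a * float(active_force_length(lm_norm)) * _FV0
            + float(passive_force_length(lm_norm))
        ) * cosa
        return ft - fiber

    lo, hi = 0.2 * params.l_m_opt, 2.0 * params.l_m_opt
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise RuntimeError(
            f"static equilibrium not bracketed for lmt={lmt:.4f} m "
            f"(residuals {r_lo:.3g}, {r_hi:.3g})"
        )
    return float(brentq(residual, lo, hi, xtol=tol))
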