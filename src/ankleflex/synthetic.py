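"""Synthetic slow-walking gait cycles with pelvis push/pull perturbations.

Generates desk-scale trials with the mechanical structure the controller and
the identification procedure assume: a smooth periodic ankle-angle template,
a double-hump vertical-GRF template calibrated to body-weight support, a
COM-velocity-deviation channel from a point-mass response to a square force
pulse at the pelvis, and a target ankle-moment channel produced by forward
simulation under known ("true") reflex gains.  Templates are analytic, so the
package needs no data download; they emulate walking at 0.6-0.62 m/s but make
no claim of matching any individual's gait.

Perturbations follow the two experimental protocols: 150 ms pulses of 4, 8,
12 or 16 % body weight applied at contralateral toe-off (the identification
dataset) and 200 ms pulses of 12 % body weight at heel strike (the
exoskeleton protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .muscle import GRAVITY
from .reflex import ReflexGains
from .simulate import AnkleModel, GaitTrial, TrialLabel, simulate_trial

__all__ = [
    "GeneratorConfig",
    "default_true_gains",
    "ankle_angle_template",
    "grf_template",
    "com_deviation_response",
    "make_steady_cycle",
    "make_perturbed_cycle",
    "make_identification_dataset",
]


def default_true_gains() -> ReflexGains:
    """Physiologically plausible ground-truth gains for the generator.

    Signs follow the reflex semantics: positive soleus force feedback and COM
    gain (push -> more plantarflexion), negative dorsiflexor COM gain and
    soleus->tibialis inhibition.  Magnitudes are in the range reported for
    reflex-based walking models (force gain of order 1/f_max, length gain of
    order 1/l_m_opt).
    """
    return ReflexGains(
        e_sol_0=0.027,
        G_sol=1.8e-4,
        K_sol=0.4,
        e_ta_0=0.01,
        G_ta=11.0,
        lm_off=0.07,
        G_sol_ta=-1.0e-4,
        K_ta=-0.2,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions emulated by the generator.

    ``magnitudes`` are fractions of body weight; ``onset_phase`` places the
    pulse at contralateral toe-off (~12 % of the ipsilateral cycle) for the
    identification protocol; heel-strike onsets use ``onset_phase=0``.
    The seed is mandatory for reproducibility.
    """

    seed: int
    speed: float = 0.62  # m/s
    cycle_duration: float = 1.4  # s (stride time at slow walking)
    dt: float = 0.001  # s
    mass: float = 70.0  # kg
    height: float = 1.75  # m
    noise_moment: float = 0.0  # N*m, additive white noise on the target
    noise_kinematics: float = 0.0  # rad / N multiplier-free channel noise
    magnitudes: tuple = (0.04, 0.08, 0.12, 0.16)
    pulse_duration: float = 0.150  # s
    onset_phase: float = 0.12  # fraction of cycle (contralateral toe-off)
    recovery_tau: float = 0.5  # s, first-order decay of the COM deviation
    n_steady: int = 8
    n_repeats: int = 2
    validation_magnitude: float = 0.12
    true_gains: ReflexGains = field(default_factory=default_true_gains)
    model: AnkleModel = field(default_factory=AnkleModel.default)

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


# periodic ankle-angle template (plantarflexion positive): brief early-stance
# plantarflexion, progressive dorsiflexion through mid-stance, push-off
# plantarflexion peak near 62 %, near-neutral swing
_PHASE_KNOTS = np.array([0.0, 8.0, 30.0, 45.0, 62.0, 75.0, 90.0, 100.0])
_ANGLE_KNOTS_DEG = np.array([3.0, 7.0, -4.0, -10.0, 15.0, -2.0, -1.0, 3.0])
_ANGLE_SPLINE = CubicSpline(_PHASE_KNOTS, np.deg2rad(_ANGLE_KNOTS_DEG), bc_type="periodic")

# GRF template constants: smooth stance window times (base + two humps),
# peak ~1.1 body weight, per-leg stride integral ~0.5 m g T
_STANCE_END = 62.0  # % of cycle
_RAMP = 4.0  # % smoothstep rise/fall
_GRF_BASE = 0.424
_GRF_AMP = 0.676
_GRF_CENTERS = (17.0, 46.0)
_GRF_SIGMA = 7.0


def ankle_angle_template(phase):
    """Ankle angle [rad] vs. gait phase [%], plantarflexion positive."""
    return _ANGLE_SPLINE(np.asarray(phase, dtype=float) % 100.0)


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def grf_template(phase, mass: float):
    """Vertical GRF [N] of the reference leg vs. gait phase [%]."""
    p = np.asarray(phase, dtype=float) % 100.0
    w = _smoothstep(p / _RAMP) * _smoothstep((_STANCE_END - p) / _RAMP)
    shape = _GRF_BASE
    for c in _GRF_CENTERS:
        shape = shape + _GRF_AMP * np.exp(-0.5 * ((p - c) / _GRF_SIGMA) ** 2)
    return mass * GRAVITY * w * shape


def com_deviation_response(
    cfg: GeneratorConfig, direction: str, magnitude: float
) -> np.ndarray:
    """Forward COM-velocity deviation [m/s] of a point mass to the pulse.

    The pelvis force is a square pulse of ``magnitude`` x body weight lasting
    ``pulse_duration`` starting at ``onset_phase``; the deviation decays back
    with a first-order recovery (time constant ``recovery_tau``) representing
    the balance-restoring response:  dv' = F/m - dv / tau.
    """
    if direction not in ("push", "pull"):
        raise ValueError(f"direction must be 'push' or 'pull', got {direction!r}")
    n = int(round(cfg.cycle_duration / cfg.dt))
    t = np.arange(n) * cfg.dt
    sign = 1.0 if direction == "push" else -1.0
    f_amp = sign * magnitude * cfg.mass * GRAVITY
    onset = cfg.onset_phase * cfg.cycle_duration
    force = np.where((t >= onset) & (t < onset + cfg.pulse_duration), f_amp, 0.0)
    dv = np.zeros(n)
    for i in range(1, n):
        dv[i] = dv[i - 1] + cfg.dt * (force[i - 1] / cfg.mass - dv[i - 1] / cfg.recovery_tau)
    return dv


def _base_channels(cfg: GeneratorConfig, rng: Optional[np.random.Generator]):
    n = int(round(cfg.cycle_duration / cfg.dt))
    t = np.arange(n) * cfg.dt
    phase = 100.0 * t / cfg.cycle_duration
    q = np.asarray(ankle_angle_template(phase))
    fz = np.asarray(grf_template(phase, cfg.mass))
    if rng is not None and cfg.noise_kinematics > 0:
        q = q + rng.normal(0.0, cfg.noise_kinematics, n)
        fz = np.maximum(fz + rng.normal(0.0, cfg.noise_kinematics * cfg.mass * GRAVITY, n), 0.0)
    return t, q, fz


def _finish_trial(cfg, t, q, fz, dcom, label, rng) -> GaitTrial:
    trial = GaitTrial(
        time=t, q=q, fz=fz, dcom=dcom, mass=cfg.mass, height=cfg.height, label=label
    )
    sim = simulate_trial(trial, cfg.true_gains, cfg.model, use_com_feedback=True)
    moment = sim.moment.copy()
    if rng is not None and cfg.noise_moment > 0:
        moment = moment + rng.normal(0.0, cfg.noise_moment, trial.n)
    trial.moment = moment
    return trial


def make_steady_cycle(
    cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> GaitTrial:
    """One steady-state gait cycle with a zero COM-deviation channel."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t, q, fz = _base_channels(cfg, rng)
    dcom = np.zeros_like(t)
    return _finish_trial(cfg, t, q, fz, dcom, TrialLabel(kind="steady"), rng)


def make_perturbed_cycle(
    cfg: GeneratorConfig,
    direction: str,
    magnitude: float,
    rng: Optional[np.random.Generator] = None,
    validation: bool = False,
) -> GaitTrial:
    """One perturbed cycle; magnitude 0 degenerates to the steady cycle."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t, q, fz = _base_channels(cfg, rng)
    if magnitude == 0.0:
        dcom = np.zeros_like(t)
        label = TrialLabel(kind="steady")
    else:
        dcom = com_deviation_response(cfg, direction, magnitude)
        label = TrialLabel(
            kind="perturbed",
            direction=direction,
            magnitude=magnitude,
            onset_time=cfg.onset_phase * cfg.cycle_duration,
            validation=validation,
        )
    return _finish_trial(cfg, t, q, fz, dcom, label, rng)


def make_identification_dataset(cfg: GeneratorConfig) -> list:
    """The identification protocol: 8 steady + 16 perturbed + 2 validation.

    Perturbed trials cover the full factorial of two directions x four
    magnitudes x two repetitions; the two validation trials (one per
    direction) are at ``cfg.validation_magnitude`` and flagged so that fits
    exclude them.
    """
    rng = np.random.default_rng(cfg.seed)
    trials = []
    for _ in range(cfg.n_steady):
        trials.append(make_steady_cycle(cfg, rng))
    for magnitude in cfg.magnitudes:
        for direction in ("push", "pull"):
            for _ in range(cfg.n_repeats):
                trials.append(make_perturbed_cycle(cfg, direction, magnitude, rng))
    for direction in ("push", "pull"):
        trials.append(
            make_perturbed_cycle(
                cfg, direction, cfg.validation_magnitude, rng, validation=True
            )
        )
    return trials
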