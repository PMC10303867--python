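"""Closed-loop forward simulation of the two-muscle ankle model.

One call integrates a whole gait trial (shooting per cycle) with forward
Euler at a fixed step (default 1 ms).  Excitations come from the reflex laws,
driven by the simulation's own delayed plantarflexor force and dorsiflexor
fiber length plus the trial's delayed COM-velocity-deviation channel.  The
module also provides the moment-tracking RMSE used by parameter
identification and the exoskeleton assistance law (a fixed fraction of the
model moment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .geometry import AnkleGeometry
from .muscle import MuscleTendonParams, init_fiber_length, E_MIN
from .reflex import ReflexGains

__all__ = [
    "AnkleModel",
    "TrialLabel",
    "GaitTrial",
    "SimResult",
    "simulate_trial",
    "moment_rmse",
    "exo_assist",
    "REF_MASS",
    "REF_HEIGHT",
]

# reference anthropometry used when scaling moments for between-subject
# comparison: an average subject of 70 kg and 1.75 m
REF_MASS = 70.0
REF_HEIGHT = 1.75


def _default_plantarflexor() -> MuscleTendonParams:
    # lumped soleus + gastrocnemius: f_max is the sum of the three heads
    return MuscleTendonParams(
        f_max=5790.0, l_m_opt=0.050, l_t_slack=0.250, v_m_max=10.0, alpha_opt=0.4538
    )


def _default_dorsiflexor() -> MuscleTendonParams:
    return MuscleTendonParams(
        f_max=905.0, l_m_opt=0.098, l_t_slack=0.223, v_m_max=10.0, alpha_opt=0.0873
    )


@dataclass(frozen=True)
class AnkleModel:
    """Muscle constants and ankle geometry bundled for simulation."""

    plantarflexor: MuscleTendonParams = field(default_factory=_default_plantarflexor)
    dorsiflexor: MuscleTendonParams = field(default_factory=_default_dorsiflexor)
    geometry: AnkleGeometry = field(default_factory=AnkleGeometry)

    @classmethod
    def default(cls) -> "AnkleModel":
        return cls()


@dataclass(frozen=True)
class TrialLabel:
    """Steady-state / perturbed annotation of one gait cycle."""

    kind: str = "steady"  # "steady" | "perturbed"
    direction: Optional[str] = None  # "push" | "pull"
    magnitude: Optional[float] = None  # fraction of body weight
    onset_time: Optional[float] = None  # s from trial start
    validation: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("steady", "perturbed"):
            raise ValueError(f"kind must be 'steady' or 'perturbed', got {self.kind!r}")
        if self.kind == "perturbed" and self.direction not in ("push", "pull"):
            raise ValueError("perturbed trials need direction 'push' or 'pull'")


@dataclass
class GaitTrial:
    """One gait cycle's synchronized input and target time series.

    Channels: time [s] at fixed dt, ankle angle q [rad, plantarflexion
    positive], vertical GRF F_z [N], COM-velocity deviation [m/s] (a zero
    channel is allowed) and, optionally, the inverse-dynamics target ankle
    moment [N*m].
    """

    time: np.ndarray
    q: np.ndarray
    fz: np.ndarray
    dcom: np.ndarray
    moment: Optional[np.ndarray] = None
    mass: float = REF_MASS
    height: float = REF_HEIGHT
    label: TrialLabel = field(default_factory=TrialLabel)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        self.dcom = np.asarray(self.dcom, dtype=float)
        n = len(self.time)
        for name in ("q", "fz", "dcom"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time length")
        if self.moment is not None:
            self.moment = np.asarray(self.moment, dtype=float)
            if len(self.moment) != n:
                raise ValueError("moment channel length != time length")
        if n < 2:
            raise ValueError("trial needs at least two samples")
        dts = np.diff(self.time)
        if not np.allclose(dts, dts[0], rtol=0, atol=1e-9):
            raise ValueError("time channel must have a constant step")
        if not (self.mass > 0 and self.height > 0):
            raise ValueError("mass and height must be > 0")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n(self) -> int:
        return len(self.time)


@dataclass
class SimResult:
    """Per-step outputs of one simulated trial."""

    e_sol: np.ndarray
    e_ta: np.ndarray
    a_sol: np.ndarray
    a_ta: np.ndarray
    lm_sol: np.ndarray
    lm_ta: np.ndarray
    F_sol: np.ndarray
    F_ta: np.ndarray
    moment: np.ndarray
    gate: np.ndarray


def _delay_samples(tau: float, dt: float) -> int:
    d = tau / dt
    if abs(d - round(d)) > 1e-6:
        raise ValueError(f"delay {tau} s is not an integer multiple of dt = {dt} s")
    return int(round(d))


def _muscle_array(p: MuscleTendonParams) -> np.ndarray:
    return np.array(
        [p.f_max, p.l_m_opt, p.l_t_slack, p.v_m_max, p.alpha_opt, p.tau_act, p.tau_deact, p.damping]
    )


def simulate_trial(
    trial: GaitTrial,
    gains: ReflexGains,
    model: Optional[AnkleModel] = None,
    use_com_feedback: bool = True,
) -> SimResult:
    """Simulate one gait trial; deterministic given identical inputs.

    With ``use_com_feedback=False`` the COM terms are omitted from the
    excitations entirely (the default-model controller); with nonzero COM
    gains and a zero deviation channel the two paths coincide.
    """
    if model is None:
        model = AnkleModel.default()
    if not (np.all(np.isfinite(trial.q)) and np.all(np.isfinite(trial.fz)) and np.all(np.isfinite(trial.dcom))):
        raise ValueError("trial channels must be finite")
    dt = trial.dt
    d_m = _delay_samples(gains.tau_m, dt)
    d_com = _delay_samples(gains.tau_com, dt)

    a0_pf = float(np.clip(gains.e_sol_0, E_MIN, 1.0))
    a0_ta = float(np.clip(gains.e_ta_0, E_MIN, 1.0))
    q0 = float(trial.q[0])
    lm0_pf = init_fiber_length(a0_pf, float(model.geometry.mtu_length(q0, "pf")), model.plantarflexor)
    lm0_ta = init_fiber_length(a0_ta, float(model.geometry.mtu_length(q0, "df")), model.dorsiflexor)

    out = _kernel.simulate_kernel(
        np.ascontiguousarray(trial.q),
        np.ascontiguousarray(trial.fz),
        np.ascontiguousarray(trial.dcom),
        dt,
        trial.mass,
        _muscle_array(model.plantarflexor),
        _muscle_array(model.dorsiflexor),
        np.asarray(model.geometry.pf_coeffs, dtype=float),
        np.asarray(model.geometry.df_coeffs, dtype=float),
        gains.as_array(),
        d_m,
        d_com,
        a0_pf,
        lm0_pf,
        a0_ta,
        lm0_ta,
        use_com_feedback,
    )
    res = SimResult(*out)
    if not np.all(np.isfinite(res.moment)):
        step = int(np.flatnonzero(~np.isfinite(res.moment))[0])
        raise RuntimeError(f"muscle equilibrium produced non-finite force at step {step}")
    return res


def moment_scale(mass: float, height: float) -> float:
    """Scale factor normalizing moments to the 70 kg / 1.75 m reference subject."""
    return (REF_MASS * REF_HEIGHT) / (mass * height)


def moment_rmse(sim: SimResult, trial: GaitTrial, scale_to_reference: bool = True) -> float:
    """RMSE between simulated and target ankle moment [N*m].

    With scaling enabled, both signals are multiplied by
    (70 kg * 1.75 m) / (mass * height) before differencing, so that errors are
    comparable between subjects.
    """
    if trial.moment is None:
        raise ValueError("trial has no target moment channel")
    s = moment_scale(trial.mass, trial.height) if scale_to_reference else 1.0
    err = s * (sim.moment - trial.moment)
    return float(np.sqrt(np.mean(err * err)))


def exo_assist(moment, fraction: float = 0.30):
    """Assistive exoskeleton moment: a fixed fraction of the model moment."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction!r}")
    return np.asarray(moment, dtype=float) * fraction
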