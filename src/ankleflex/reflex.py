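"""Gait-phase-gated reflex laws with delayed COM-velocity feedback.

The plantarflexor ("soleus") excitation combines a baseline with delayed
positive force feedback and delayed feedback of the deviation of forward COM
velocity from its steady-state cycle, both active during stance only:

    e_sol(t) = e_sol_0 + K_Fz * G_sol * F_sol(t - tau_m)
                       + K_Fz * K_sol * dCOMv(t - tau_com)

The dorsiflexor ("tibialis anterior") excitation combines a baseline, an
ungated fiber-length feedback, stance-gated inhibition proportional to the
delayed plantarflexor force, and stance-gated COM-velocity feedback:

    e_ta(t) = e_ta_0 + G_ta * (lm_ta(t - tau_m) - lm_off)
                     + K_Fz * G_sol_ta * F_sol(t - tau_m)
                     + K_Fz * K_ta * dCOMv(t - tau_com)

The stance gate K_Fz is a smooth function of the vertical ground reaction
force, K_Fz = 0.5*tanh(10*(F_z/(m*g) - 0.4)) + 0.5, approaching 1 in stance
and 0 in swing.  Local (spinal) feedback is delayed by tau_m = 30 ms; the
supra-spinal COM pathway by tau_com = 60 ms.  Gains are stored signed: the
inhibition gain G_sol_ta and the dorsiflexor COM gain K_ta are expected to be
negative, with no hidden negation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

from .muscle import E_MIN, GRAVITY

__all__ = [
    "ReflexGains",
    "DelayLine",
    "stance_gate",
    "soleus_excitation",
    "tibialis_excitation",
    "clamp_excitation",
    "delayed",
    "GAIN_NAMES",
]

#: canonical parameter names, reused verbatim in config files and JSON output
GAIN_NAMES = (
    "e_sol_0",
    "G_sol",
    "K_sol",
    "e_ta_0",
    "G_ta",
    "lm_off",
    "G_sol_ta",
    "K_ta",
)


@dataclass(frozen=True)
class ReflexGains:
    """The eight control parameters plus the two feedback delays.

    Units: baselines dimensionless; G_sol, G_sol_ta in 1/N; G_ta in 1/m;
    lm_off in m; K_sol, K_ta in s/m; delays in s.
    """

    e_sol_0: float = 0.027
    G_sol: float = 0.0
    K_sol: float = 0.0
    e_ta_0: float = 0.01
    G_ta: float = 0.0
    lm_off: float = 0.07
    G_sol_ta: float = 0.0
    K_ta: float = 0.0
    tau_m: float = 0.030
    tau_com: float = 0.060

    def __post_init__(self) -> None:
        vals = [getattr(self, n) for n in GAIN_NAMES + ("tau_m", "tau_com")]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite reflex parameter")
        if self.tau_m < 0 or self.tau_com < 0:
            raise ValueError("delays must be >= 0")
        for n in ("e_sol_0", "e_ta_0"):
            if not 0.0 <= getattr(self, n) <= 1.0:
                raise ValueError(f"{n} must be in [0, 1]")

    def as_array(self) -> np.ndarray:
        """Gains in canonical order (delays excluded)."""
        return np.array([getattr(self, n) for n in GAIN_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReflexGains":
        return cls(**d)

    def replace(self, **kw) -> "ReflexGains":
        return replace(self, **kw)

    def without_com_feedback(self) -> "ReflexGains":
        """The reduced (default-model) gain set with K_sol = K_ta = 0."""
        return self.replace(K_sol=0.0, K_ta=0.0)


def clamp_excitation(e):
    """Clamp excitation(s) to the shared range [E_MIN, 1]."""
    return np.clip(e, E_MIN, 1.0)


def stance_gate(F_z, m: float):
    """Smooth stance/swing gate from the vertical GRF (raw forces allowed)."""
    if not m > 0:
        raise ValueError(f"mass must be > 0, got {m!r}")
    F_z = np.asarray(F_z, dtype=float)
    return 0.5 * np.tanh(10.0 * (F_z / (m * GRAVITY) - 0.4)) + 0.5


def soleus_excitation(F_sol_delayed, dcom_delayed, gate, gains: ReflexGains):
    """Plantarflexor excitation from delayed force and COM-velocity feedback."""
    e = (
        gains.e_sol_0
        + gate * gains.G_sol * F_sol_delayed
        + gate * gains.K_sol * dcom_delayed
    )
    return clamp_excitation(e)


def tibialis_excitation(
    lm_ta_delayed, F_sol_delayed, dcom_delayed, gate, gains: ReflexGains
):
    """Dorsiflexor excitation; the length term is not gated by stance."""
    e = (
        gains.e_ta_0
        + gains.G_ta * (lm_ta_delayed - gains.lm_off)
        + gate * gains.G_sol_ta * F_sol_delayed
        + gate * gains.K_ta * dcom_delayed
    )
    return clamp_excitation(e)


class DelayLine:
    """Pure transport delay on a uniformly sampled signal.

    ``read(i)`` returns the sample written at index ``i - delay`` once
    available and the fill value before that.  The fill value defaults to the
    first written sample (steady-state hold), which avoids artificial
    transients at trial start.
    """

    def __init__(self, delay_samples: int, fill: float | None = None):
        if delay_samples < 0 or int(delay_samples) != delay_samples:
            raise ValueError(f"delay must be a non-negative integer, got {delay_samples!r}")
        self.delay = int(delay_samples)
        self._fill = fill
        self._buf: list[float] = []

    def write(self, x: float) -> None:
        if self._fill is None:
            self._fill = float(x)
        self._buf.append(float(x))

    def read(self, t_index: int) -> float:
        if t_index < 0:
            raise IndexError(f"negative time index {t_index}")
        j = t_index - self.delay
        if j < 0:
            if self._fill is None:
                raise RuntimeError("delay line read before any write and no fill value")
            return self._fill
        return self._buf[j]

    def push(self, x: float) -> float:
        """Write the next sample and return the delayed output at that time."""
        self.write(x)
        return self.read(len(self._buf) - 1)


def delayed(signal: DelayLine, t_index: int) -> float:
    """Read a delay line at ``t_index`` (exact shift by the configured delay)."""
    return signal.read(t_index)
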