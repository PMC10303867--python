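"""COM-velocity reference ("signal learner") and deviation computation.

Turns a pelvis-marker trajectory into the feedback signal of the balance
controller: causal differentiation and band-pass filtering of the forward
position, gait-event detection from the vertical GRF, a rolling phase-indexed
lookup table of the mean forward COM velocity over the most recent six
unperturbed cycles, and the deviation of the measured velocity from that
reference at the current gait phase.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

__all__ = [
    "GaitEvents",
    "ComReference",
    "detect_heel_strike",
    "filter_com_velocity",
    "resample_to_phase",
    "update_reference",
    "com_deviation",
    "PHASE_GRID",
]

#: fixed phase grid of the reference table: 1001 points over [0, 100] %,
#: matching ~1 s cycles sampled at 1 kHz
PHASE_GRID = np.linspace(0.0, 100.0, 1001)

HEEL_STRIKE_THRESHOLD = 50.0  # N
REFRACTORY = 0.5  # s, minimum spacing between events of the same kind


@dataclass
class GaitEvents:
    """Heel-strike / toe-off sample indices and per-sample gait phase [%]."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        for name in ("heel_strikes", "toe_offs"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, idx)
        self.phase = np.asarray(self.phase, dtype=float)


def detect_heel_strike(
    fz: np.ndarray,
    fs: float,
    threshold: float = HEEL_STRIKE_THRESHOLD,
    refractory: float = REFRACTORY,
) -> GaitEvents:
    """Gait events from rising/falling crossings of a vertical-GRF threshold.

    Heel strikes are rising crossings of ``threshold`` (default 50 N) and
    toe-offs the falling crossings, both debounced by a refractory period.
    The per-sample phase ramps linearly from 0 to 100 % between consecutive
    heel strikes (extrapolated with the neighbouring cycle duration at the
    edges) and resets to 0 exactly at each heel strike.
    """
    fz = np.asarray(fz, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = fz >= threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    falling = np.flatnonzero(~above[1:] & above[:-1]) + 1

    def debounce(idx: np.ndarray) -> np.ndarray:
        if len(idx) == 0:
            return idx
        keep = [idx[0]]
        gap = refractory * fs
        for i in idx[1:]:
            if i - keep[-1] >= gap:
                keep.append(i)
        return np.asarray(keep)

    hs = debounce(rising)
    to = debounce(falling)
    if len(hs) == 0:
        raise ValueError("no heel strikes: vertical GRF never crosses the threshold")

    n = len(fz)
    phase = np.empty(n)
    if len(hs) == 1:
        # single event: assume a nominal period spanning the record
        period = float(n)
        starts = [hs[0] - period, float(hs[0]), hs[0] + period]
    else:
        periods = np.diff(hs).astype(float)
        starts = [hs[0] - periods[0], *hs.astype(float), hs[-1] + periods[-1]]
    starts = np.asarray(starts, dtype=float)
    for k in range(len(starts) - 1):
        s, e = starts[k], starts[k + 1]
        lo = max(int(np.ceil(s)), 0)
        hi = min(int(np.ceil(e)), n)
        if lo < hi:
            idx = np.arange(lo, hi)
            phase[idx] = 100.0 * (idx - s) / (e - s)
    phase = np.clip(phase, 0.0, 100.0 - 1e-12)
    return GaitEvents(heel_strikes=hs, toe_offs=to, phase=phase)


def filter_com_velocity(
    marker_pos: np.ndarray,
    fs: float,
    band: tuple = (5.0, 50.0),
    order: int = 2,
    ripple_db: float = 0.140,
) -> np.ndarray:
    """Causal velocity estimate from a marker position, as used in real time.

    Backward-difference differentiation followed by a causal Chebyshev-I
    band-pass (second-order sections) with the given corners and passband
    ripple.  Intended for the online controller path; the offline
    identification path uses unfiltered mocap-derived velocity, since a 5 Hz
    high-pass removes the near-DC content of the deviation signal.
    """
    if fs <= 2.0 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for a {band[1]} Hz corner")
    pos = np.asarray(marker_pos, dtype=float)
    vel = np.empty_like(pos)
    vel[0] = 0.0
    vel[1:] = np.diff(pos) * fs
    sos = design_com_filter(fs, band, order, ripple_db)
    return sig.sosfilt(sos, vel)


def design_com_filter(fs, band=(5.0, 50.0), order=2, ripple_db=0.140):
    """The second-order-sections band-pass used by :func:`filter_com_velocity`."""
    return sig.cheby1(order, ripple_db, band, btype="bandpass", fs=fs, output="sos")


def resample_to_phase(values: np.ndarray, grid: np.ndarray = PHASE_GRID) -> np.ndarray:
    """Resample one cycle's samples onto the fixed phase grid (linear)."""
    values = np.asarray(values, dtype=float)
    src = np.linspace(0.0, 100.0, len(values))
    return np.interp(grid, src, values)


@dataclass
class ComReference:
    """Rolling phase-indexed reference of forward COM velocity.

    The lookup table is the pointwise mean of the most recent ``window``
    unperturbed cycles (FIFO), each resampled to the fixed phase grid.
    """

    window: int = 6
    grid: np.ndarray = field(default_factory=lambda: PHASE_GRID.copy())
    _cycles: deque = field(default_factory=deque, repr=False)

    @property
    def n_cycles(self) -> int:
        return len(self._cycles)

    @property
    def table(self) -> np.ndarray:
        if not self._cycles:
            raise RuntimeError("COM reference not initialized (no cycles yet)")
        return np.mean(np.vstack(self._cycles), axis=0)

    def add_cycle(self, velocity: np.ndarray) -> None:
        """Ingest one unperturbed cycle (any length; resampled to the grid)."""
        v = np.asarray(velocity, dtype=float)
        if len(v) != len(self.grid):
            v = resample_to_phase(v, self.grid)
        self._cycles.append(v)
        while len(self._cycles) > self.window:
            self._cycles.popleft()

    def predict(self, phase):
        """Reference velocity at the given phase(s) [%], linear interpolation."""
        return np.interp(np.asarray(phase, dtype=float) % 100.0, self.grid, self.table)


def update_reference(
    ref: ComReference, new_cycle: np.ndarray, perturbed: bool = False
) -> ComReference:
    """Add one cycle to the rolling reference; perturbed cycles are rejected.

    Cycles in which a perturbation occurred — and, by the caller's labelling,
    the first recovery cycle after one — must not enter the learner.
    """
    if perturbed:
        warnings.warn("perturbed cycle rejected by the COM reference learner")
        return ref
    ref.add_cycle(new_cycle)
    return ref


def com_deviation(v_meas, phase, ref: ComReference):
    """Deviation of the measured forward COM velocity from the reference."""
    if ref.n_cycles == 0:
        raise RuntimeError("COM reference not initialized (need >= 1 cycle)")
    return np.asarray(v_meas, dtype=float) - ref.predict(phase)
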