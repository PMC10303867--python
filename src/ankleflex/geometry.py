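"""Polynomial ankle geometry: joint angle -> muscle-tendon length, moment arm.

The musculotendon length of each muscle is a polynomial in the ankle angle q
(plantarflexion positive, radians), lmt(q) = sum_i c_i q^i, as commonly fitted
to musculoskeletal models such as gait2392.  The moment arm is the exact
analytic derivative r(q) = -d lmt / d q, so a muscle that shortens with
increasing q (the plantarflexor) has a positive moment arm and produces a
positive (plantarflexion) moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnkleGeometry", "ankle_moment"]


def _polyval(coeffs: np.ndarray, q):
    """Evaluate ascending-order polynomial (Horner)."""
    q = np.asarray(q, dtype=float)
    y = np.zeros_like(q)
    for c in coeffs[::-1]:
        y = y * q + c
    return y


def _polyder_val(coeffs: np.ndarray, q):
    q = np.asarray(q, dtype=float)
    y = np.zeros_like(q)
    n = len(coeffs)
    for k in range(n - 1, 0, -1):
        y = y * q + k * coeffs[k]
    return y


@dataclass(frozen=True)
class AnkleGeometry:
    """Polynomial length models for the plantarflexor and dorsiflexor.

    Coefficients are ascending (c0, c1, ...).  ``plantarflexion_positive``
    records the angle sign convention of the data the polynomials were fitted
    in; data in a dorsiflexion-positive convention must be negated on load.
    """

    pf_coeffs: tuple = field(default=(0.295, -0.05, -0.005, 0.006667, 0.0))
    df_coeffs: tuple = field(default=(0.320, 0.04, -0.0025, 0.0, 0.0))
    plantarflexion_positive: bool = True

    def _coeffs(self, muscle: str) -> np.ndarray:
        if muscle in ("pf", "plantarflexor"):
            return np.asarray(self.pf_coeffs, dtype=float)
        if muscle in ("df", "dorsiflexor"):
            return np.asarray(self.df_coeffs, dtype=float)
        raise ValueError(f"unknown muscle {muscle!r}")

    def mtu_length(self, q, muscle: str):
        """Musculotendon length lmt(q) [m]."""
        return _polyval(self._coeffs(muscle), q)

    def moment_arm(self, q, muscle: str):
        """Moment arm r(q) = -d lmt/dq [m] (plantarflexion-positive moment)."""
        return -_polyder_val(self._coeffs(muscle), q)


def ankle_moment(q, F_pf, F_df, geom: AnkleGeometry):
    """Total ankle moment r_pf(q)*F_pf + r_df(q)*F_df [N*m], plantarflexion +.

    Forces must be non-negative (muscles pull only).
    """
    q = np.asarray(q, dtype=float)
    F_pf = np.asarray(F_pf, dtype=float)
    F_df = np.asarray(F_df, dtype=float)
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(F_pf)) and np.all(np.isfinite(F_df))):
        raise ValueError("non-finite input to ankle_moment")
    if np.any(F_pf < 0) or np.any(F_df < 0):
        raise ValueError("muscle forces must be >= 0")
    return geom.moment_arm(q, "pf") * F_pf + geom.moment_arm(q, "df") * F_df
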