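"""Reflex-gain identification by multi-trial moment tracking (shooting).

The free gains are estimated by minimizing the sum over trials of the mean
squared difference between the simulated and the inverse-dynamics ankle
moment, both scaled to a 70 kg / 1.75 m reference subject.  Each trial is
forward-simulated in full (shooting per cycle) and the bounded nonlinear
least-squares problem is solved with a trust-region reflective method using
central finite-difference gradients, from several seeded starting points.

Baseline soleus activity is fixed (e_sol_0 = 0.027) by default because it is
strongly interdependent with the soleus force-feedback gain; the
interdependence of the remaining parameters is quantified from the residual
Jacobian at the optimum (correlation matrix of the linearized estimator,
entries with |r| > 0.9 flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .reflex import ReflexGains, GAIN_NAMES
from .simulate import AnkleModel, GaitTrial, SimResult, simulate_trial, moment_rmse

__all__ = [
    "FitResult",
    "fit_gains",
    "cross_validate",
    "parameter_correlations",
    "correlation_from_jacobian",
    "flag_correlated",
    "default_bounds",
    "FREE_DEFAULT",
    "CORR_FLAG_THRESHOLD",
]

#: free parameters of the standard identification (e_sol_0 held fixed)
FREE_DEFAULT = ("G_sol", "K_sol", "e_ta_0", "G_ta", "lm_off", "G_sol_ta", "K_ta")

CORR_FLAG_THRESHOLD = 0.9


def default_bounds(model: Optional[AnkleModel] = None) -> dict:
    """Physiological sign-respecting box bounds for each gain."""
    if model is None:
        model = AnkleModel.default()
    l_opt = model.dorsiflexor.l_m_opt
    return {
        "e_sol_0": (0.0, 0.3),
        "G_sol": (0.0, 5e-3),
        "K_sol": (0.0, 5.0),
        "e_ta_0": (0.0, 0.3),
        "G_ta": (0.0, 100.0),
        "lm_off": (0.5 * l_opt, 1.5 * l_opt),
        "G_sol_ta": (-5e-3, 0.0),
        "K_ta": (-5.0, 0.0),
    }


@dataclass
class FitResult:
    """Estimated gains with diagnostics.

    ``rmse`` maps 'steady' / 'perturbed' / 'validation' to per-trial RMSE
    lists [N*m, reference-scaled]; ``correlation`` is the parameter
    correlation matrix of the free gains at the optimum.
    """

    gains: ReflexGains
    objective: float
    free: tuple
    rmse: dict = field(default_factory=dict)
    correlation: Optional[pd.DataFrame] = None
    flagged_pairs: list = field(default_factory=list)
    converged: bool = False
    nfev: int = 0
    n_starts: int = 0
    seed: int = 0
    config: dict = field(default_factory=dict)

    def rmse_mean(self, key: str) -> float:
        vals = self.rmse.get(key, [])
        return float(np.mean(vals)) if len(vals) else float("nan")

    def to_dict(self) -> dict:
        return {
            "gains": self.gains.to_dict(),
            "objective": self.objective,
            "free": list(self.free),
            "rmse": {k: list(map(float, v)) for k, v in self.rmse.items()},
            "rmse_mean": {k: self.rmse_mean(k) for k in self.rmse},
            "correlation": None
            if self.correlation is None
            else self.correlation.round(6).to_dict(),
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "converged": self.converged,
            "nfev": self.nfev,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "config": self.config,
        }


def _gains_from_vector(
    x: np.ndarray, free: Sequence[str], base: ReflexGains
) -> ReflexGains:
    return base.replace(**{name: float(v) for name, v in zip(free, x)})


def _residual_builder(
    trials: Sequence[GaitTrial],
    free: Sequence[str],
    base: ReflexGains,
    model: AnkleModel,
    use_com_feedback: bool,
):
    """Residual vector: per-trial scaled moment errors, weighted 1/sqrt(n)
    so every trial contributes its mean squared error with equal weight."""
    from .simulate import moment_scale

    pre = [(t, moment_scale(t.mass, t.height), 1.0 / np.sqrt(t.n)) for t in trials]

    def residuals(x: np.ndarray) -> np.ndarray:
        gains = _gains_from_vector(x, free, base)
        parts = []
        for trial, scale, w in pre:
            sim = simulate_trial(trial, gains, model, use_com_feedback)
            parts.append(w * scale * (sim.moment - trial.moment))
        return np.concatenate(parts)

    return residuals


def _split_rmse(
    trials: Sequence[GaitTrial],
    gains: ReflexGains,
    model: AnkleModel,
    use_com_feedback: bool,
) -> dict:
    out = {"steady": [], "perturbed": [], "validation": []}
    for t in trials:
        if t.moment is None:
            continue
        sim = simulate_trial(t, gains, model, use_com_feedback)
        r = moment_rmse(sim, t)
        if t.label.validation:
            out["validation"].append(r)
        elif t.label.kind == "steady":
            out["steady"].append(r)
        else:
            out["perturbed"].append(r)
    return out


def fit_gains(
    trials: Sequence[GaitTrial],
    model: Optional[AnkleModel] = None,
    free: Sequence[str] = FREE_DEFAULT,
    fixed: Optional[dict] = None,
    bounds: Optional[dict] = None,
    n_starts: int = 5,
    seed: int = 0,
    use_com_feedback: bool = True,
    max_nfev: Optional[int] = 3000,
    base_gains: Optional[ReflexGains] = None,
    compute_correlations: bool = True,
) -> FitResult:
    """Estimate the free reflex gains over the training trials.

    Validation-flagged trials are excluded from the objective but their RMSE
    under the fitted gains is reported.  Fixing a gain simply removes it from
    the decision vector (no re-parameterization): ``fixed`` entries and
    ``base_gains`` provide its value.  Deterministic for a given seed.
    """
    if model is None:
        model = AnkleModel.default()
    train = [t for t in trials if t.moment is not None and not t.label.validation]
    if not train:
        raise ValueError("need at least one non-validation trial with a target moment")
    free = tuple(free)
    unknown = set(free) - set(GAIN_NAMES)
    if unknown:
        raise ValueError(f"unknown gain names: {sorted(unknown)}")
    base = base_gains if base_gains is not None else ReflexGains()
    if fixed:
        base = base.replace(**fixed)
    if not use_com_feedback:
        free = tuple(n for n in free if n not in ("K_sol", "K_ta"))
        base = base.without_com_feedback()

    all_bounds = default_bounds(model)
    if bounds:
        all_bounds.update(bounds)
    lb = np.array([all_bounds[n][0] for n in free])
    ub = np.array([all_bounds[n][1] for n in free])
    widths = np.maximum(ub - lb, 1e-12)

    residuals = _residual_builder(train, free, base, model, use_com_feedback)
    n_per_trial = len(train)  # residual cost -> sum over trials of MSE

    # Multi-start with a cheap cost prefilter: excitation saturation creates
    # large flat plateaus (e.g. a strongly positive tibialis length feedback
    # clamps e_ta at 1 over most of its box), on which a local solver stalls.
    # Seeded uniform draws are therefore over-sampled, ranked by one objective
    # evaluation each, and only the most promising ones are polished.
    rng = np.random.default_rng(seed)
    n_starts = max(n_starts, 1)
    pool = lb + widths * rng.uniform(0.0, 1.0, size=(8 * n_starts, len(free)))
    pool_cost = []
    for x in pool:
        try:
            r = residuals(x)
            pool_cost.append(0.5 * float(r @ r))
        except RuntimeError:
            pool_cost.append(np.inf)
    order = np.argsort(pool_cost)[:n_starts]

    best = None
    total_nfev = len(pool)
    for k in order:
        if not np.isfinite(pool_cost[k]):
            continue
        try:
            sol = least_squares(
                residuals,
                pool[k],
                jac="3-point",
                bounds=(lb, ub),
                x_scale=widths,
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
                max_nfev=max_nfev,
            )
        except RuntimeError as exc:  # simulation blow-up along the path
            warnings.warn(f"start discarded: {exc}")
            continue
        total_nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
        # an essentially exact fit cannot be improved by further starts
        if best.cost < 1e-12 * max(min(pool_cost), 1.0):
            break
    if best is None:
        raise RuntimeError("all optimization starts failed")

    gains = _gains_from_vector(best.x, free, base)
    objective = float(2.0 * best.cost)  # sum over trials of mean squared error
    result = FitResult(
        gains=gains,
        objective=objective,
        free=free,
        rmse=_split_rmse(trials, gains, model, use_com_feedback),
        converged=bool(best.status > 0),
        nfev=total_nfev,
        n_starts=max(n_starts, 1),
        seed=seed,
        config={
            "fixed": dict(fixed or {}),
            "bounds": {n: list(all_bounds[n]) for n in free},
            "use_com_feedback": use_com_feedback,
            "n_trials": n_per_trial,
            "max_nfev": max_nfev,
        },
    )
    if not result.converged:
        warnings.warn("optimizer did not converge; FitResult flagged")
    if compute_correlations and result.converged:
        corr = parameter_correlations(result, train, model=model)
        result.correlation = corr
        result.flagged_pairs = flag_correlated(corr)
    return result


def flag_correlated(corr: pd.DataFrame, threshold: float = CORR_FLAG_THRESHOLD) -> list:
    """Off-diagonal pairs with |r| above the interdependence threshold."""
    names = list(corr.index)
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr.iloc[i, j]) > threshold:
                flagged.append((names[i], names[j]))
    return flagged


def parameter_correlations(
    fit: FitResult,
    trials: Sequence[GaitTrial],
    model: Optional[AnkleModel] = None,
    free: Optional[Sequence[str]] = None,
    rel_step: float = 1e-6,
) -> pd.DataFrame:
    """Parameter-correlation matrix of the linearized estimator at the optimum.

    The residual Jacobian J is formed by central finite differences; the
    covariance is proportional to (J'J)^-1 and is normalized to a correlation
    matrix.  A rank-deficient J'J (exactly collinear parameters) is handled
    with a pseudo-inverse.  ``free`` may extend the fitted set, e.g. to probe
    the interdependence of a gain that was held fixed.
    """
    if model is None:
        model = AnkleModel.default()
    free = tuple(free) if free is not None else fit.free
    train = [t for t in trials if t.moment is not None and not t.label.validation]
    use_com = fit.config.get("use_com_feedback", True)
    residuals = _residual_builder(train, free, fit.gains, model, use_com)
    x = np.array([getattr(fit.gains, n) for n in free])
    r0 = residuals(x)
    J = np.empty((len(r0), len(x)))
    for k in range(len(x)):
        h = rel_step * max(abs(x[k]), 1e-3)
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        J[:, k] = (residuals(xp) - residuals(xm)) / (2.0 * h)
    return correlation_from_jacobian(J, list(free))


def correlation_from_jacobian(J: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    """Correlation matrix of the linearized least-squares estimator.

    Columns with (near-)zero norm belong to parameters the residuals are
    insensitive to (flat objective directions); they are listed in
    ``result.attrs['unidentifiable']`` and their correlations set to NaN.
    """
    J = np.asarray(J, dtype=float)
    norms = np.linalg.norm(J, axis=0)
    dead = norms < 1e-10 * max(norms.max(), 1e-300)
    live = ~dead
    n = J.shape[1]
    corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    if live.any():
        jtj = J[:, live].T @ J[:, live]
        try:
            cov = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            cov = np.linalg.pinv(jtj)
        d = np.sqrt(np.maximum(np.diag(cov), 1e-300))
        sub = cov / np.outer(d, d)
        np.fill_diagonal(sub, 1.0)
        idx = np.flatnonzero(live)
        corr[np.ix_(idx, idx)] = sub
    out = pd.DataFrame(corr, index=list(names), columns=list(names))
    out.attrs["unidentifiable"] = [names[k] for k in np.flatnonzero(dead)]
    return out


def cross_validate(
    trials: Sequence[GaitTrial],
    held_out_magnitude: float,
    **fit_kwargs,
) -> FitResult:
    """Fit on all magnitudes except one; report RMSE on the held-out trials.

    Steady-state trials always stay in the training set.  The held-out trials
    are not refitted: their RMSE under the trained gains is stored under
    ``rmse['validation']``.
    """
    mags = {
        t.label.magnitude
        for t in trials
        if t.label.kind == "perturbed" and t.label.magnitude is not None
    }
    if held_out_magnitude not in mags:
        raise ValueError(
            f"held-out magnitude {held_out_magnitude} not present (have {sorted(mags)})"
        )

    def is_held_out(t: GaitTrial) -> bool:
        return t.label.kind == "perturbed" and t.label.magnitude == held_out_magnitude

    relabeled = []
    for t in trials:
        if is_held_out(t):
            t = GaitTrial(
                time=t.time,
                q=t.q,
                fz=t.fz,
                dcom=t.dcom,
                moment=t.moment,
                mass=t.mass,
                height=t.height,
                label=t.label.__class__(
                    kind=t.label.kind,
                    direction=t.label.direction,
                    magnitude=t.label.magnitude,
                    onset_time=t.label.onset_time,
                    validation=True,
                ),
            )
        relabeled.append(t)
    return fit_gains(relabeled, **fit_kwargs)
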