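"""YAML configuration: defaults, schema validation, object construction.

An empty file (or no file) yields the full defaults.  Unknown keys are
rejected so that typos fail loudly.  Key documented defaults: dt = 0.001 s,
tau_m = 0.030 s, tau_com = 0.060 s, e_sol_0 = 0.027, assistance fraction
0.30, heel-strike threshold 50 N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import AnkleGeometry
from .reflex import ReflexGains, GAIN_NAMES
from .simulate import AnkleModel
from .synthetic import GeneratorConfig, default_true_gains

__all__ = ["Config", "ConfigError", "load_config", "default_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_MUSCLE_KEYS = {
    "f_max",
    "l_m_opt",
    "l_t_slack",
    "v_m_max",
    "alpha_opt",
    "tau_act",
    "tau_deact",
    "damping",
}

_SCHEMA = {
    "simulation": {"dt"},
    "gains": set(GAIN_NAMES) | {"tau_m", "tau_com"},
    "muscles": {"plantarflexor", "dorsiflexor"},
    "geometry": {"plantarflexor", "dorsiflexor", "plantarflexion_positive"},
    "events": {"heel_strike_threshold", "refractory"},
    "exo": {"assist_fraction"},
    "com_filter": {"band", "order", "ripple_db"},
    "generator": {
        "seed",
        "speed",
        "cycle_duration",
        "mass",
        "height",
        "noise_moment",
        "noise_kinematics",
        "magnitudes",
        "pulse_duration",
        "onset_phase",
        "recovery_tau",
        "n_steady",
        "n_repeats",
        "validation_magnitude",
    },
    "estimation": {"n_starts", "seed", "free", "fixed", "bounds", "max_nfev"},
}


@dataclass
class Config:
    """Validated parameter sets for all modules (plain dicts per section)."""

    simulation: dict = field(default_factory=dict)
    gains: dict = field(default_factory=dict)
    muscles: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    exo: dict = field(default_factory=dict)
    com_filter: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.simulation.get("dt", 0.001))

    def reflex_gains(self, true_gains: bool = False) -> ReflexGains:
        base = default_true_gains() if true_gains else ReflexGains()
        return base.replace(**self.gains)

    def ankle_model(self) -> AnkleModel:
        default = AnkleModel.default()
        pf = default.plantarflexor.replace(**self.muscles.get("plantarflexor", {}))
        ta = default.dorsiflexor.replace(**self.muscles.get("dorsiflexor", {}))
        gkw = {}
        if "plantarflexor" in self.geometry:
            gkw["pf_coeffs"] = tuple(self.geometry["plantarflexor"])
        if "dorsiflexor" in self.geometry:
            gkw["df_coeffs"] = tuple(self.geometry["dorsiflexor"])
        if "plantarflexion_positive" in self.geometry:
            gkw["plantarflexion_positive"] = bool(self.geometry["plantarflexion_positive"])
        return AnkleModel(plantarflexor=pf, dorsiflexor=ta, geometry=AnkleGeometry(**gkw))

    def generator_config(self, seed: int | None = None) -> GeneratorConfig:
        kw = dict(self.generator)
        if seed is not None:
            kw["seed"] = seed
        if "seed" not in kw:
            raise ConfigError("generator seed is mandatory (set generator.seed or --seed)")
        if "magnitudes" in kw:
            kw["magnitudes"] = tuple(kw["magnitudes"])
        kw["dt"] = self.dt
        kw["true_gains"] = self.reflex_gains(true_gains=True)
        kw["model"] = self.ankle_model()
        return GeneratorConfig(**kw)

    @property
    def assist_fraction(self) -> float:
        return float(self.exo.get("assist_fraction", 0.30))

    @property
    def heel_strike_threshold(self) -> float:
        return float(self.events.get("heel_strike_threshold", 50.0))

    def estimation_kwargs(self) -> dict:
        kw = {}
        est = self.estimation
        if "n_starts" in est:
            kw["n_starts"] = int(est["n_starts"])
        if "seed" in est:
            kw["seed"] = int(est["seed"])
        if "free" in est:
            kw["free"] = tuple(est["free"])
        if "fixed" in est:
            kw["fixed"] = dict(est["fixed"])
        if "bounds" in est:
            kw["bounds"] = {k: tuple(v) for k, v in est["bounds"].items()}
        if "max_nfev" in est:
            kw["max_nfev"] = int(est["max_nfev"])
        return kw


def _check_keys(raw: dict) -> None:
    unknown_sections = set(raw) - set(_SCHEMA)
    if unknown_sections:
        raise ConfigError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, keys in raw.items():
        if keys is None:
            continue
        if not isinstance(keys, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(keys) - _SCHEMA[section]
        if bad:
            raise ConfigError(f"unknown key(s) in {section!r}: {sorted(bad)}")
    for muscle, entries in (raw.get("muscles") or {}).items():
        bad = set(entries or {}) - _MUSCLE_KEYS
        if bad:
            raise ConfigError(f"unknown muscle key(s) in {muscle!r}: {sorted(bad)}")


def _validate(cfg: Config) -> Config:
    dt = cfg.dt
    if dt <= 0:
        raise ConfigError("simulation.dt must be > 0")
    gains = cfg.reflex_gains()
    for name, tau in (("tau_m", gains.tau_m), ("tau_com", gains.tau_com)):
        if abs(tau / dt - round(tau / dt)) > 1e-6:
            raise ConfigError(f"gains.{name} = {tau} s is not a multiple of dt = {dt} s")
    frac = cfg.assist_fraction
    if not 0.0 <= frac <= 1.0:
        raise ConfigError("exo.assist_fraction must be in [0, 1]")
    if cfg.heel_strike_threshold <= 0:
        raise ConfigError("events.heel_strike_threshold must be > 0")
    mags = cfg.generator.get("magnitudes", ())
    if any(m <= 0 for m in mags):
        raise ConfigError("generator.magnitudes must be positive")
    try:
        cfg.ankle_model()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def load_config(path=None) -> Config:
    """Load and validate a YAML config; ``None`` or an empty file = defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded
    _check_keys(raw)
    cfg = Config(**{k: dict(v) for k, v in raw.items() if v})
    return _validate(cfg)


def default_config() -> Config:
    return _validate(Config())
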