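"""Flat YAML configuration for reproducible runs.

Schema (units: hours, mL, counts).  Required: ``p``, ``c``, ``tau_E``,
``tau_I``, ``n_E``, ``n_I``, ``N_cells`` and exactly one of ``beta`` or
``R0``.  Optional: ``gamma`` (default 1), ``s`` (default 1), ``V0``
(default 1), ``I0`` (default 0), ``antiviral_mode`` + ``antiviral_efficacy``,
``p_events``, ``seed``, ``max_time``.  Unknown keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .params import (
    AntiviralIntervention,
    InfectionParameters,
    apply_antiviral,
)
from .simulate import SimulatorConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_from_dict"]

_REQUIRED = ("p", "c", "tau_E", "tau_I", "n_E", "n_I", "N_cells")
_PARAM_OPTIONAL = ("beta", "R0", "gamma", "s", "V0", "I0")
_SIM_KEYS = ("p_events", "seed", "max_time")
_AV_KEYS = ("antiviral_mode", "antiviral_efficacy")
_ALL_KEYS = set(_REQUIRED) | set(_PARAM_OPTIONAL) | set(_SIM_KEYS) | set(_AV_KEYS)

_INT_KEYS = ("n_E", "n_I", "N_cells", "V0", "I0")


@dataclass(frozen=True)
class RunConfig:
    """A fully validated, serializable run configuration."""

    params: InfectionParameters
    intervention: Optional[AntiviralIntervention]
    sim: SimulatorConfig

    @property
    def effective_params(self) -> InfectionParameters:
        """Parameters with the antiviral (if any) applied."""
        if self.intervention is None:
            return self.params
        return apply_antiviral(self.params, self.intervention)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self.params, k)
            for k in (
                "beta",
                "p",
                "c",
                "gamma",
                "tau_E",
                "tau_I",
                "n_E",
                "n_I",
                "N_cells",
                "s",
                "V0",
                "I0",
            )
        }
        if self.intervention is not None:
            d["antiviral_mode"] = self.intervention.mode.value
            d["antiviral_efficacy"] = self.intervention.efficacy
        d["p_events"] = self.sim.p_events
        if self.sim.seed is not None:
            d["seed"] = self.sim.seed
        d["max_time"] = self.sim.max_time
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance blocks."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict) or not raw:
        raise ValueError(
            "empty configuration; required keys: "
            + ", ".join(_REQUIRED)
            + ", and one of beta/R0"
        )
    unknown = sorted(set(raw) - _ALL_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
    missing = sorted(k for k in _REQUIRED if k not in raw)
    if missing:
        raise ValueError(f"missing required key(s): {', '.join(missing)}")
    if ("beta" in raw) == ("R0" in raw):
        raise ValueError("exactly one of 'beta' or 'R0' must be given")

    kw = {}
    for k in _REQUIRED + _PARAM_OPTIONAL:
        if k in raw and k != "R0":
            kw[k] = int(raw[k]) if k in _INT_KEYS else raw[k]
    try:
        if "R0" in raw:
            params = InfectionParameters.from_R0(float(raw["R0"]), **kw)
        else:
            params = InfectionParameters(**kw)
    except ValueError as exc:
        raise ValueError(f"invalid parameter value: {exc}") from exc

    iv = None
    if "antiviral_mode" in raw or "antiviral_efficacy" in raw:
        if not ("antiviral_mode" in raw and "antiviral_efficacy" in raw):
            raise ValueError(
                "antiviral_mode and antiviral_efficacy must be given together"
            )
        iv = AntiviralIntervention(
            mode=raw["antiviral_mode"], efficacy=float(raw["antiviral_efficacy"])
        )

    sim_kw = {k: raw[k] for k in _SIM_KEYS if k in raw}
    if "seed" in sim_kw:
        sim_kw["seed"] = int(sim_kw["seed"])
    sim = SimulatorConfig(**sim_kw)
    return RunConfig(params=params, intervention=iv, sim=sim)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
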