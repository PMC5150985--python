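"""Run configuration: unit-checked YAML/JSON parsing.

Every dimensioned quantity in a config file must carry an explicit unit
("30 mg", "7.5 mm", "50 um", "100 rad/s"), converted to SI at parse time; a
bare number for a dimensioned field is rejected to prevent magnitude errors.
Unknown keys anywhere in the file are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .physics import AuditInputs, FluidProperties, InsectMorphology
from .dynamics import SolverOptions

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_quantity"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


# multiplicative factors to SI
_UNIT_FACTORS = {
    "kg": 1.0, "g": 1e-3, "mg": 1e-6, "ug": 1e-9,
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "μm": 1e-6,
    "s": 1.0, "ms": 1e-3,
    "m/s": 1.0, "mm/s": 1e-3, "cm/s": 1e-2,
    "m/s^2": 1.0,
    "rad/s": 1.0,
    "kg/m^3": 1.0, "g/cm^3": 1e3,
    "N/m": 1.0, "mN/m": 1e-3,
    "Pa.s": 1.0, "Pa*s": 1.0, "Pa·s": 1.0, "mPa.s": 1e-3,
    "Pa": 1.0, "MPa": 1e6, "GPa": 1e9,
    "J": 1.0, "mJ": 1e-3, "uJ": 1e-6, "nJ": 1e-9,
    "Hz": 1.0, "1/s": 1.0,
}


def parse_quantity(raw, dimensionless: bool = False) -> float:
    """Parse '``<value> <unit>``' to an SI float.

    Dimensionless fields accept bare numbers; dimensioned fields must name a
    unit from the supported table.
    """
    if isinstance(raw, (int, float)):
        if dimensionless:
            return float(raw)
        raise ConfigError(
            f"bare number {raw!r}: dimensioned quantities need an explicit unit"
        )
    parts = str(raw).split()
    if len(parts) != 2:
        raise ConfigError(f"cannot parse quantity {raw!r}; expected '<value> <unit>'")
    value, unit = parts
    if unit not in _UNIT_FACTORS:
        raise ConfigError(f"unknown unit {unit!r} in {raw!r}")
    try:
        return float(value) * _UNIT_FACTORS[unit]
    except ValueError as exc:
        raise ConfigError(f"bad numeric value in {raw!r}") from exc


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{name}' block: {sorted(unknown)}")


@dataclass(frozen=True)
class SweepConfig:
    M_values: tuple[float, ...] = (0.5,)
    L_min: float = 1.0
    L_max: float = 7.0
    L_n: int = 61
    Omega_min: float = 0.2
    Omega_max: float = 6.0
    Omega_n: int = 117


@dataclass(frozen=True)
class SynthConfig:
    template: str = "medium"
    fps: float = 1000.0
    noise: float = 0.02
    n: int = 10
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for the pipeline commands."""

    fluid: FluidProperties = FluidProperties()
    morphology: InsectMorphology | None = None
    omega: float | None = None
    Omega: float | None = None
    sweep: SweepConfig = SweepConfig()
    synth: SynthConfig = SynthConfig()
    solver: SolverOptions = SolverOptions()
    include_weight: bool = False
    initial_depth: float = 1.0e-6
    audit: AuditInputs = AuditInputs()
    output_dir: str = "striderjump_out"


def _parse_fluid(block: dict) -> FluidProperties:
    _check_keys(block, {"density", "surface_tension", "viscosity", "gravity"}, "fluid")
    kw = {}
    for key in block:
        kw[key] = parse_quantity(block[key])
    return FluidProperties(**kw)


def _parse_morphology(block: dict) -> InsectMorphology:
    allowed = {"body_mass", "leg_length", "support_length", "leg_radius",
               "rest_height", "cuticle_modulus", "name"}
    _check_keys(block, allowed, "morphology")
    kw = {}
    for key, raw in block.items():
        kw[key] = raw if key == "name" else parse_quantity(raw)
    return InsectMorphology(**kw)


def _parse_behaviour(block: dict) -> tuple[float | None, float | None]:
    _check_keys(block, {"omega", "Omega"}, "behaviour")
    omega = parse_quantity(block["omega"]) if "omega" in block else None
    Omega = parse_quantity(block["Omega"], dimensionless=True) if "Omega" in block else None
    return omega, Omega


def _parse_sweep(block: dict) -> SweepConfig:
    allowed = {"M_values", "L_min", "L_max", "L_n", "Omega_min", "Omega_max", "Omega_n"}
    _check_keys(block, allowed, "sweep")
    kw: dict = {}
    if "M_values" in block:
        kw["M_values"] = tuple(float(v) for v in block["M_values"])
    for key in allowed - {"M_values"}:
        if key in block:
            v = block[key]
            kw[key] = int(v) if key.endswith("_n") else parse_quantity(v, dimensionless=True)
    return SweepConfig(**kw)


def _parse_synth(block: dict) -> SynthConfig:
    allowed = {"template", "fps", "noise", "n", "seed"}
    _check_keys(block, allowed, "synth")
    kw: dict = {}
    for key in block:
        if key == "template":
            kw[key] = str(block[key])
        elif key in ("n", "seed"):
            kw[key] = int(block[key])
        else:
            kw[key] = parse_quantity(block[key], dimensionless=True)
    return SynthConfig(**kw)


def _parse_audit(block: dict) -> AuditInputs:
    allowed = {"wetted_length", "descent_speed", "dimple_depth", "takeoff_speed",
               "detachment_energy", "n_legs"}
    _check_keys(block, allowed, "audit")
    kw: dict = {}
    for key, raw in block.items():
        kw[key] = int(raw) if key == "n_legs" else parse_quantity(raw)
    return AuditInputs(**kw)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    allowed = {"fluid", "morphology", "behaviour", "sweep", "synth", "solver",
               "audit", "output_dir"}
    _check_keys(data, allowed, "top level")

    kw: dict = {}
    if "fluid" in data:
        kw["fluid"] = _parse_fluid(data["fluid"] or {})
    if "morphology" in data:
        kw["morphology"] = _parse_morphology(data["morphology"] or {})
    if "behaviour" in data:
        kw["omega"], kw["Omega"] = _parse_behaviour(data["behaviour"] or {})
    if "sweep" in data:
        kw["sweep"] = _parse_sweep(data["sweep"] or {})
    if "synth" in data:
        kw["synth"] = _parse_synth(data["synth"] or {})
    if "solver" in data:
        block = data["solver"] or {}
        _check_keys(block, {"method", "rtol", "atol", "max_step", "n_dense",
                            "initial_depth", "include_weight"}, "solver")
        opt_kw = {k: block[k] for k in ("method", "rtol", "atol", "max_step", "n_dense")
                  if k in block}
        kw["solver"] = SolverOptions(**opt_kw)
        if "include_weight" in block:
            kw["include_weight"] = bool(block["include_weight"])
        if "initial_depth" in block:
            kw["initial_depth"] = float(block["initial_depth"])
    if "audit" in data:
        kw["audit"] = _parse_audit(data["audit"] or {})
    if "output_dir" in data:
        kw["output_dir"] = str(data["output_dir"])
    return RunConfig(**kw)


def config_hash(path: str | Path) -> str:
    """SHA-256 of the canonicalized config content (for run manifests)."""
    import hashlib

    data = yaml.safe_load(Path(path).read_text()) or {}
    canon = json.dumps(data, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
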