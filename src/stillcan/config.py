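"""Run configuration: strict TOML schema with process defaults.

An empty file (or no file) yields the full default study configuration:
100 °C / 20 min heating, 20 °C / 20 min cooling from 20 °C, the fitted
syrup property polynomials, peach constants, z = 11.5 °C, T_ref = 90 °C,
D_ref = 1.1 min.  Unknown keys are rejected by name; every physical
quantity carries its unit in the key name.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Tuple

from .geometry import CASE_NAMES
from .lethality import LethalityParams
from .pipeline import CaseConfig
from .properties import PropertyModel, default_property_model
from .solver import Probe, ProcessPhase, SolverConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Validated, flattened run configuration (units in the field names)."""

    case_name: str = "upward"
    spacing_mm: float = 2.5
    symmetry: bool = False
    initial_T_C: float = 20.0
    heating_T_C: float = 100.0
    heating_min: float = 20.0
    cooling_T_C: float = 20.0
    cooling_min: float = 20.0

    courant_target: float = 0.5
    dt_cap_s: float = 0.5
    pressure_tolerance: float = 1e-6
    max_pressure_iterations: int = 500
    flow_enabled: bool = True

    lethality_T_ref_C: float = 90.0
    lethality_z_C: float = 11.5
    lethality_D_ref_min: float = 1.1
    lethality_log_reductions: float = 6.0

    gravity_m_s2: float = 9.81
    density_as_printed: bool = False

    output_directory: str = "stillcan_out"
    snapshot_every_s: float = 0.0
    log_level: str = "info"

    probes: Tuple[Probe, ...] = ()

    def to_case_config(self) -> CaseConfig:
        return CaseConfig(
            case_name=self.case_name,
            spacing=self.spacing_mm / 1000.0,
            symmetry=self.symmetry,
            heating=ProcessPhase(self.heating_T_C, self.heating_min * 60.0),
            cooling=ProcessPhase(self.cooling_T_C, self.cooling_min * 60.0),
            initial_T=self.initial_T_C,
            solver=SolverConfig(
                courant_target=self.courant_target,
                dt_cap=self.dt_cap_s,
                pressure_tolerance=self.pressure_tolerance,
                max_pressure_iterations=self.max_pressure_iterations,
                flow_enabled=self.flow_enabled,
            ),
            lethality=LethalityParams(
                T_ref=self.lethality_T_ref_C,
                z=self.lethality_z_C,
                D_ref=self.lethality_D_ref_min,
                log_reductions=self.lethality_log_reductions,
            ),
            probes=self.probes,
        )

    def to_property_model(self) -> PropertyModel:
        return default_property_model(
            as_printed=self.density_as_printed,
            gravity_magnitude=self.gravity_m_s2,
        )


_SCHEMA: Dict[str, Dict[str, type]] = {
    "case": {
        "name": str, "spacing_mm": float, "symmetry": bool,
        "initial_T_C": float, "heating_T_C": float, "heating_min": float,
        "cooling_T_C": float, "cooling_min": float,
    },
    "solver": {
        "courant_target": float, "dt_cap_s": float,
        "pressure_tolerance": float, "max_pressure_iterations": int,
        "flow_enabled": bool,
    },
    "lethality": {
        "T_ref_C": float, "z_C": float, "D_ref_min": float,
        "log_reductions": float,
    },
    "properties": {"gravity_m_s2": float, "density_as_printed": bool},
    "output": {
        "directory": str, "snapshot_every_s": float, "log_level": str,
    },
}

_POSITIVE = {
    "spacing_mm", "heating_min", "cooling_min", "dt_cap_s",
    "pressure_tolerance", "z_C", "D_ref_min", "gravity_m_s2",
}

_FIELD_MAP = {
    ("case", "name"): "case_name",
    ("solver", "courant_target"): "courant_target",
    ("solver", "dt_cap_s"): "dt_cap_s",
    ("solver", "pressure_tolerance"): "pressure_tolerance",
    ("solver", "max_pressure_iterations"): "max_pressure_iterations",
    ("solver", "flow_enabled"): "flow_enabled",
    ("lethality", "T_ref_C"): "lethality_T_ref_C",
    ("lethality", "z_C"): "lethality_z_C",
    ("lethality", "D_ref_min"): "lethality_D_ref_min",
    ("lethality", "log_reductions"): "lethality_log_reductions",
    ("properties", "gravity_m_s2"): "gravity_m_s2",
    ("properties", "density_as_printed"): "density_as_printed",
    ("output", "directory"): "output_directory",
    ("output", "snapshot_every_s"): "snapshot_every_s",
    ("output", "log_level"): "log_level",
}
for _k in _SCHEMA["case"]:
    _FIELD_MAP.setdefault(("case", _k), _k)


def _coerce(section: str, key: str, value: Any) -> Any:
    expected = _SCHEMA[section][key]
    if expected is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"'{section}.{key}' must be a number")
        value = float(value)
        if key in _POSITIVE and value <= 0:
            raise ConfigError(f"'{section}.{key}' must be positive")
        return value
    if expected is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"'{section}.{key}' must be an integer")
        return value
    if expected is bool:
        if not isinstance(value, bool):
            raise ConfigError(f"'{section}.{key}' must be true/false")
        return value
    if not isinstance(value, str):
        raise ConfigError(f"'{section}.{key}' must be a string")
    return value


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration; defaults fill the gaps."""
    raw = Path(path).read_bytes()
    try:
        data = tomllib.loads(raw.decode("utf-8"))
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"not valid TOML: {exc}") from exc
    return config_from_dict(data)


def config_from_dict(data: Dict[str, Any]) -> RunConfig:
    kwargs: Dict[str, Any] = {}
    for section, content in data.items():
        if section == "probes":
            kwargs["probes"] = _parse_probes(content)
            continue
        if section not in _SCHEMA:
            raise ConfigError(f"unknown section '{section}'")
        if not isinstance(content, dict):
            raise ConfigError(f"section '{section}' must be a table")
        for key, value in content.items():
            if key not in _SCHEMA[section]:
                raise ConfigError(f"unknown key '{section}.{key}'")
            kwargs[_FIELD_MAP[(section, key)]] = _coerce(section, key, value)
    if "case_name" in kwargs and kwargs["case_name"] not in CASE_NAMES:
        raise ConfigError(f"'case.name' must be one of {CASE_NAMES}")
    return RunConfig(**kwargs)


def _parse_probes(content: Any) -> Tuple[Probe, ...]:
    if not isinstance(content, list):
        raise ConfigError("'probes' must be an array of tables")
    probes: List[Probe] = []
    for i, entry in enumerate(content):
        if not isinstance(entry, dict):
            raise ConfigError("'probes' entries must be tables")
        allowed = {"id", "x_mm", "y_mm", "z_mm"}
        extra = set(entry) - allowed
        if extra:
            raise ConfigError(f"unknown key 'probes.{sorted(extra)[0]}'")
        try:
            probes.append(
                Probe(
                    probe_id=str(entry.get("id", f"probe{i}")),
                    x_mm=float(entry["x_mm"]),
                    y_mm=float(entry["y_mm"]),
                    z_mm=float(entry["z_mm"]),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"probe {i} is missing {exc}") from exc
    return tuple(probes)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def save_config(config: RunConfig, path) -> None:
    """Write a RunConfig as TOML; ``load_config`` round-trips it exactly."""
    lines: List[str] = []
    inverse: Dict[str, Tuple[str, str]] = {f: sk for sk, f in _FIELD_MAP.items()}
    by_section: Dict[str, List[Tuple[str, Any]]] = {}
    for fname, value in asdict(config).items():
        if fname == "probes":
            continue
        section, key = inverse[fname]
        by_section.setdefault(section, []).append((key, value))
    for section in _SCHEMA:
        if section not in by_section:
            continue
        lines.append(f"[{section}]")
        for key, value in by_section[section]:
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    for probe in config.probes:
        lines.append("[[probes]]")
        lines.append(f'id = "{probe.probe_id}"')
        lines.append(f"x_mm = {probe.x_mm!r}")
        lines.append(f"y_mm = {probe.y_mm!r}")
        lines.append(f"z_mm = {probe.z_mm!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
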