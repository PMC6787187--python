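"""Run-configuration parsing (TOML) with schema validation and defaults.

The config has sections ``geometry``, ``material``, ``solver``,
``quantify`` and ``output``.  Unknown keys are rejected with their key
path; defaults are filled exactly as documented per module, and the fully
resolved config can be re-serialised so a saved copy re-parses to the
identical object.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .errors import ConfigError
from .geometry import PillarLayout, build_square_layout
from .mechanics import MaterialParams
from .solver import ActivationSchedule, ContactParams, SolverOptions

_SCHEMA: dict[str, dict[str, Any]] = {
    "geometry": {
        "lattice": "square",
        "n_x": 4,
        "n_y": 4,
        "pillar_diameter_um": 400.0,
        "pillar_height_um": 200.0,
        "interval_um": 200.0,
        "substrate_mm": None,  # [width, height] or absent
        "element_size_um": 50.0,
    },
    "material": {
        "E": 1.9,
        "nu": 0.3,
        "beta": 2.0,
        "active_mode": "active_pressure",
    },
    "solver": {
        "eta_max": 1.0,
        "n_steps": 20,
        "newton_tol": 1e-8,
        "max_newton_iters": 40,
        "penalty_scale": 1e3,
        "max_penetration_frac": 1e-3,
        "spring_scale": 1e-6,
    },
    "quantify": {
        "method": "otsu",
        "threshold": None,
        "min_size_px": 0,
        "ring_px": 2,
        "cover_frac": 0.10,
        "pixel_size_um": 2.0,
    },
    "output": {
        "write_vtk": True,
        "write_csv": True,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration (every key present)."""

    sections: dict[str, dict[str, Any]]

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]

    def layout(self) -> PillarLayout:
        g = self.sections["geometry"]
        if g["lattice"] != "square":
            raise ConfigError("only square lattices can be built from a config")
        bounds = None
        if g["substrate_mm"] is not None:
            w, h = (float(v) * 1000.0 for v in g["substrate_mm"])
            bounds = (0.0, 0.0, w, h)
        return build_square_layout(
            int(g["n_x"]), int(g["n_y"]), float(g["pillar_diameter_um"]),
            float(g["interval_um"]), bounds, height=float(g["pillar_height_um"]),
        )

    def material(self) -> MaterialParams:
        m = self.sections["material"]
        return MaterialParams(float(m["E"]), float(m["nu"]), float(m["beta"]),
                              m["active_mode"])

    def schedule(self) -> ActivationSchedule:
        s = self.sections["solver"]
        return ActivationSchedule.uniform(float(s["eta_max"]), int(s["n_steps"]))

    def contact(self) -> ContactParams:
        s = self.sections["solver"]
        return ContactParams(penalty_scale=float(s["penalty_scale"]),
                             max_penetration_frac=float(s["max_penetration_frac"]))

    def solver_options(self) -> SolverOptions:
        s = self.sections["solver"]
        return SolverOptions(newton_tol=float(s["newton_tol"]),
                             max_newton_iters=int(s["max_newton_iters"]),
                             spring_scale=float(s["spring_scale"]))

    def to_toml(self) -> str:
        lines = []
        for section, keys in self.sections.items():
            lines.append(f"[{section}]")
            for key, value in keys.items():
                if value is None:
                    continue
                lines.append(f"{key} = {_toml_value(value)}")
            lines.append("")
        return "\n".join(lines)


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ConfigError(f"cannot serialise config value {value!r}")


def _validate(resolved: dict[str, dict[str, Any]]) -> None:
    m = resolved["material"]
    if not (-1.0 < float(m["nu"]) < 0.5):
        raise ConfigError(f"[material].nu = {m['nu']} outside (-1, 0.5)")
    if float(m["E"]) <= 0:
        raise ConfigError("[material].E must be positive")
    if float(m["beta"]) < 0:
        raise ConfigError("[material].beta must be non-negative")
    if m["active_mode"] not in ("as_printed", "active_pressure"):
        raise ConfigError(f"[material].active_mode = {m['active_mode']!r} unknown")
    g = resolved["geometry"]
    for key in ("pillar_diameter_um", "pillar_height_um", "interval_um",
                "element_size_um"):
        if float(g[key]) <= 0:
            raise ConfigError(f"[geometry].{key} must be positive")
    if int(g["n_x"]) < 2 or int(g["n_y"]) < 2:
        raise ConfigError("[geometry].n_x and n_y must be >= 2")
    s = resolved["solver"]
    if not (0 < float(s["eta_max"]) <= 1.0):
        raise ConfigError("[solver].eta_max must lie in (0, 1]")
    if int(s["n_steps"]) < 1:
        raise ConfigError("[solver].n_steps must be >= 1")


def resolve_config(raw: dict[str, Any]) -> RunConfig:
    """Apply defaults and validate a parsed TOML mapping."""
    resolved: dict[str, dict[str, Any]] = {}
    for section, defaults in _SCHEMA.items():
        given = raw.get(section, {})
        if not isinstance(given, dict):
            raise ConfigError(f"[{section}] must be a table")
        unknown = set(given) - set(defaults)
        if unknown:
            raise ConfigError(
                f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
            )
        resolved[section] = {**defaults, **given}
    unknown_sections = set(raw) - set(_SCHEMA)
    if unknown_sections:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown_sections))}")
    _validate(resolved)
    return RunConfig(sections=resolved)


def parse_config(path: str | Path) -> RunConfig:
    """Read and resolve a TOML config file."""
    path = Path(path)
    try:
        raw = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML in {path}: {exc}") from exc
    return resolve_config(raw)


def default_config_toml(n_x: int = 4, n_y: int = 4) -> str:
    """Fully resolved default config text for an n_x x n_y benchmark."""
    cfg = resolve_config({"geometry": {"n_x": n_x, "n_y": n_y}})
    return cfg.to_toml()
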