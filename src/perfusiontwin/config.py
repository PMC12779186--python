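"""Configuration loading and validation.

Two sets of factor bounds exist side by side:

* ``design_bounds`` — the training-campaign design space: VVD 0.5–2 d⁻¹,
  temperature shift 34–36.5 °C, stir 700–1400 rpm, pyruvate feed 0–2 g/(L·d).
* ``control_bounds`` — the search space the optimizer may command during
  closed-loop operation.  Identical except stir is capped at 1050 rpm, because
  higher agitation is deleterious for cell viability.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["DESIGN_BOUNDS", "CONTROL_BOUNDS", "validate_config", "load_config",
           "ConfigError"]

DESIGN_BOUNDS = {
    "VVD": (0.5, 2.0),
    "Temp": (34.0, 36.5),
    "Stir": (700.0, 1400.0),
    "Pyr": (0.0, 2.0),
}

CONTROL_STIR_MAX = 1050.0

CONTROL_BOUNDS = {**DESIGN_BOUNDS, "Stir": (700.0, CONTROL_STIR_MAX)}

#: state variables a closed-loop objective may target
_OBJECTIVE_VARIABLES = {"VCD", "DCD", "Via", "Diam", "Glc", "Gln", "Glu",
                        "Lac", "Amm", "Titer", "VCV"}
_OBJECTIVE_MODES = {"track", "maximize", "minimize"}


class ConfigError(ValueError):
    pass


def _check_bounds(bounds, name):
    for factor, pair in bounds.items():
        lo, hi = float(pair[0]), float(pair[1])
        if lo > hi:
            raise ConfigError(
                f"{name} bounds for {factor} inverted: ({lo}, {hi})")
        bounds[factor] = (lo, hi)
    return bounds


def validate_config(config):
    """Normalize and validate a configuration mapping.

    Fills defaults (Table-style design bounds, control stir cap, 3-day
    horizon, master seed 0) and rejects bound inversions, control bounds that
    exceed the viability-safe stir range, and unknown objective variables.
    Returns a new normalized dict; an empty objective list is valid
    (monitoring-only mode).
    """
    cfg = copy.deepcopy(dict(config or {}))
    design = {k: tuple(v) for k, v in {**DESIGN_BOUNDS,
                                       **cfg.get("design_bounds", {})}.items()}
    _check_bounds(design, "design")
    control = {k: tuple(v) for k, v in {**CONTROL_BOUNDS,
                                        **cfg.get("control_bounds", {})}.items()}
    _check_bounds(control, "control")
    if control["Stir"][1] > CONTROL_STIR_MAX:
        raise ConfigError(
            f"control-mode stir upper bound {control['Stir'][1]} rpm exceeds "
            f"{CONTROL_STIR_MAX} rpm; higher agitation is deleterious for "
            "cell viability")
    cfg["design_bounds"] = design
    cfg["control_bounds"] = control

    cfg.setdefault("horizon", 3)
    if int(cfg["horizon"]) < 1:
        raise ConfigError("horizon must be >= 1")
    cfg["horizon"] = int(cfg["horizon"])
    cfg.setdefault("seeds", {})
    cfg["seeds"].setdefault("master", 0)

    objectives = cfg.get("objectives", [])
    for obj in objectives:
        var = obj.get("variable")
        if var not in _OBJECTIVE_VARIABLES:
            raise ConfigError(f"unknown objective variable: {var!r}")
        mode = obj.setdefault("mode", "track")
        if mode not in _OBJECTIVE_MODES:
            raise ConfigError(f"unknown objective mode: {mode!r}")
        if mode == "track" and "target" not in obj:
            raise ConfigError(f"objective on {var} in track mode needs a target")
        for ctrl in obj.get("controls", []):
            if ctrl not in control:
                raise ConfigError(f"unknown control variable: {ctrl!r}")
    cfg["objectives"] = objectives
    return cfg


def load_config(path):
    """Load a YAML configuration file and validate it."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)
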