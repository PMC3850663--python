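"""Scenario configuration files and result writers.

Scenario files are plain YAML with up to four sections — ``model``,
``controller``, ``solver``, ``output`` — whose keys carry explicit unit
suffixes in clinical convention (cm, cm/hr, hours); everything is converted
to SI on load.  An empty (or absent) file reproduces the default pin-only
study scenario.  Unknown sections or keys are rejected.

Writers emit an RFC-4180 CSV time series with a fixed column order, a JSON
run summary (with a config echo and the package version), and a two-column
cervicogram table (time in hours, dilation diameter in cm).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .controller import ControlMode, ControllerConfig, M_PER_S_TO_CM_PER_HR
from .dynamics import IntegrationMethod, SimulationResult, SolverConfig
from .model_core import ModelParameters

__all__ = [
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "save_scenario",
    "write_timeseries",
    "write_summary",
    "export_cervicogram",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "t_s",
    "theta_rad",
    "sP1_m",
    "sP2_m",
    "dilation_diameter_cm",
    "effacement_cm",
    "dilation_rate_cm_per_hr",
    "K1",
    "K2",
    "F_traction_N",
    "FxR2_N",
    "FyR2_N",
    "MzP1_Nm",
]

#: error_unit name -> scale applied to the SI (m/s) rate error
ERROR_UNITS = {"cm_per_hr": M_PER_S_TO_CM_PER_HR, "si": 1.0}


class ScenarioError(ValueError):
    """Malformed or invalid scenario file."""


@dataclass(frozen=True)
class Scenario:
    """A fully validated simulation scenario (all values SI)."""

    params: ModelParameters
    controller: ControllerConfig
    solver: SolverConfig
    output_dir: Path = Path("out")


# key -> (dataclass field, factor converting file value to SI)
_MODEL_KEYS = {
    "wall_thickness_cm": ("wall_thickness_l", 1e-2),
    "initial_opening_cm": ("s_init", 1e-2),
    "quarter_mass_kg": ("quarter_mass", 1.0),
    "moment_of_inertia_kg_m2": ("Jzz", 1.0),
    "pin_damping_N_m_s_per_rad": ("B1", 1.0),
    "sliding_damping_N_s_per_m": ("B2", 1.0),
    "gravity_m_per_s2": ("g", 1.0),
    "traction_mass_kg": ("traction_mass", 1.0),
    "traction_fraction": ("traction_fraction", 1.0),
    "gravity_lever_coeff": ("gravity_lever_coeff", 1.0),
}
_CONTROLLER_KEYS = {
    "gain_pin_N_s_per_rad": ("gain_pin", 1.0),
    "gain_sliding_N_s_per_m2": ("gain_sliding", 1.0),
    "desired_diameter_rate_cm_per_hr": (
        "desired_diameter_rate",
        1.0 / M_PER_S_TO_CM_PER_HR,
    ),
    "ramp_duration_s": ("ramp_duration", 1.0),
}
_SOLVER_KEYS = {
    "abs_tol": ("abs_tol", 1.0),
    "rel_tol": ("rel_tol", 1.0),
    "max_step_s": ("max_step", 1.0),
    "t_end_hours": ("t_end", 3600.0),
    "termination_diameter_cm": ("termination_diameter", 1e-2),
    "output_interval_s": ("output_interval", 1.0),
    "baumgarte_alpha_per_s": ("baumgarte_alpha", 1.0),
    "baumgarte_beta_per_s": ("baumgarte_beta", 1.0),
}


def _numeric_section(
    raw: dict, keymap: dict, section: str, *, allow_none: tuple[str, ...] = ()
) -> dict:
    out = {}
    for key, value in raw.items():
        if key not in keymap:
            raise ScenarioError(f"unknown key {key!r} in section {section!r}")
        field_name, factor = keymap[key]
        if value is None and key in allow_none:
            out[field_name] = None
            continue
        try:
            out[field_name] = float(value) * factor
        except (TypeError, ValueError):
            raise ScenarioError(
                f"key {key!r} in section {section!r} must be numeric, "
                f"got {value!r}"
            )
    return out


def load_scenario(path: str | Path | None = None) -> Scenario:
    """Load and validate a scenario file; ``None``/empty file means defaults.

    Every default is the study value; the resolved SI parameters are logged.
    Raises :class:`ScenarioError` naming the offending key on parse
    problems, and propagates the dataclass ``ValueError`` (which names the
    violated invariant) on validation problems.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ScenarioError(f"cannot parse scenario file {path}: {exc}")
        if not isinstance(raw, dict):
            raise ScenarioError(
                f"scenario file {path} must be a mapping of sections"
            )

    known_sections = {"model", "controller", "solver", "output"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ScenarioError(f"unknown section(s): {sorted(unknown)}")

    model_kwargs = _numeric_section(
        raw.get("model") or {}, _MODEL_KEYS, "model",
        allow_none=("moment_of_inertia_kg_m2",),
    )
    params = ModelParameters(**model_kwargs)

    ctl_raw = dict(raw.get("controller") or {})
    ctl_kwargs: dict = {}
    if "mode" in ctl_raw:
        ctl_kwargs["mode"] = ControlMode.parse(str(ctl_raw.pop("mode")))
    if "error_unit" in ctl_raw:
        unit = str(ctl_raw.pop("error_unit"))
        if unit not in ERROR_UNITS:
            raise ScenarioError(
                f"unknown error_unit {unit!r}; expected one of "
                f"{sorted(ERROR_UNITS)}"
            )
        ctl_kwargs["error_unit_scale"] = ERROR_UNITS[unit]
    if "clamp_nonnegative" in ctl_raw:
        value = ctl_raw.pop("clamp_nonnegative")
        if not isinstance(value, bool):
            raise ScenarioError("clamp_nonnegative must be a boolean")
        ctl_kwargs["clamp_nonnegative"] = value
    ctl_kwargs.update(
        _numeric_section(ctl_raw, _CONTROLLER_KEYS, "controller")
    )
    controller = ControllerConfig(**ctl_kwargs)

    sol_raw = dict(raw.get("solver") or {})
    sol_kwargs: dict = {}
    if "method" in sol_raw:
        sol_kwargs["method"] = IntegrationMethod.parse(str(sol_raw.pop("method")))
    sol_kwargs.update(_numeric_section(sol_raw, _SOLVER_KEYS, "solver"))
    solver = SolverConfig(**sol_kwargs)
    solver.validate_against(params)

    out_raw = dict(raw.get("output") or {})
    unknown = set(out_raw) - {"directory"}
    if unknown:
        raise ScenarioError(f"unknown key(s) in section 'output': {sorted(unknown)}")
    output_dir = Path(out_raw.get("directory", "out"))

    logger.info(
        "scenario resolved (SI): l=%g m, m=%g kg, Jzz=%g kg m^2, mode=%s, "
        "rate setpoint=%g m/s, ramp=%g s, error scale=%g",
        params.wall_thickness_l, params.quarter_mass, params.Jzz,
        controller.mode.value, controller.desired_diameter_rate,
        controller.ramp_duration, controller.error_unit_scale,
    )
    return Scenario(params=params, controller=controller, solver=solver,
                    output_dir=output_dir)


def scenario_to_dict(scn: Scenario) -> dict:
    """Scenario in file format (clinical units); inverse of loading."""
    p, c, s = scn.params, scn.controller, scn.solver
    error_unit = next(
        (name for name, scale in ERROR_UNITS.items()
         if scale == c.error_unit_scale),
        c.error_unit_scale,
    )
    return {
        "model": {
            "wall_thickness_cm": p.wall_thickness_l * 100.0,
            "initial_opening_cm": p.s_init * 100.0,
            "quarter_mass_kg": p.quarter_mass,
            "moment_of_inertia_kg_m2": p.Jzz,
            "pin_damping_N_m_s_per_rad": p.B1,
            "sliding_damping_N_s_per_m": p.B2,
            "gravity_m_per_s2": p.g,
            "traction_mass_kg": p.traction_mass,
            "traction_fraction": p.traction_fraction,
            "gravity_lever_coeff": p.gravity_lever_coeff,
        },
        "controller": {
            "mode": c.mode.value,
            "gain_pin_N_s_per_rad": c.gain_pin,
            "gain_sliding_N_s_per_m2": c.gain_sliding,
            "desired_diameter_rate_cm_per_hr":
                c.desired_diameter_rate * M_PER_S_TO_CM_PER_HR,
            "ramp_duration_s": c.ramp_duration,
            "error_unit": error_unit,
            "clamp_nonnegative": c.clamp_nonnegative,
        },
        "solver": {
            "abs_tol": s.abs_tol,
            "rel_tol": s.rel_tol,
            "max_step_s": s.max_step,
            "t_end_hours": s.t_end / 3600.0,
            "termination_diameter_cm": s.termination_diameter * 100.0,
            "method": s.method.value,
            "output_interval_s": s.output_interval,
            "baumgarte_alpha_per_s": s.baumgarte_alpha,
            "baumgarte_beta_per_s": s.baumgarte_beta,
        },
        "output": {"directory": str(scn.output_dir)},
    }


def save_scenario(scn: Scenario, path: str | Path) -> None:
    """Write a scenario file; ``load_scenario(save_scenario(x)) == x``."""
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(scn), sort_keys=False)
    )


def write_timeseries(result: SimulationResult, path: str | Path) -> None:
    """CSV time series: fixed column order, 9 significant digits, no locale."""
    try:
        result.series[CSV_COLUMNS].to_csv(
            Path(path), index=False, float_format="%.9g"
        )
    except OSError as exc:
        raise OSError(f"cannot write time series to {path}: {exc}") from exc


def write_summary(
    result: SimulationResult, path: str | Path, scenario: Scenario | None = None
) -> None:
    """JSON run summary with config echo and software version."""
    payload = {
        "software": {"name": "cervixsim", "version": __version__},
        "method": result.method.value,
        "summary": result.summary,
        "config": scenario_to_dict(scenario) if scenario is not None else None,
    }
    try:
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write summary to {path}: {exc}") from exc


def export_cervicogram(result: SimulationResult, path: str | Path) -> float | None:
    """Two-column cervicogram (time hr, dilation cm); returns post-ramp slope.

    The slope is the secant of the dilation column between the end of the
    ramp and termination — identical, by construction, to the summary's mean
    post-ramp diameter rate.  ``None`` (JSON null in the summary) when the
    run ends inside the ramp.
    """
    table = pd.DataFrame(
        {
            "time_hr": result.series["t_s"] / 3600.0,
            "dilation_cm": result.series["dilation_diameter_cm"],
        }
    )
    try:
        table.to_csv(Path(path), index=False, float_format="%.9g")
    except OSError as exc:
        raise OSError(f"cannot write cervicogram to {path}: {exc}") from exc
    return result.summary["mean_postramp_diameter_rate_cm_per_hr"]
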