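"""Ramping protocol and the proportional compliance-feedback laws.

The induction protocol ramps two signals smoothly from zero over the first
half hour: the applied traction share and the desired dilation rate.  A
cosine smoothstep ``r(t) = 1/2 - 1/2 cos(pi t / T)`` is used for both —
C^1, monotone, flat at both ends.

Feedback converts the tracking error of the *radius* dilation rate (half
the clinically quoted diameter rate) into spring constants:

    e  = measured_radius_rate - desired_radius_rate(t)
    K1 = gain_pin     * e   (pin scenarios)
    K2 = gain_sliding * e   (sliding scenarios)

with the error expressed, by default, in cm/hr — the clinical rate unit, in
which the published gains (20 and 100000) yield spring constants of the
published magnitude.  Positive error (dilation running ahead of the
setpoint) stiffens the cervix; otherwise the springs relax to zero — the
"softening" that lets traction advance dilation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .model_core import ModelParameters, traction_force

__all__ = [
    "ControlMode",
    "ControllerConfig",
    "ramp",
    "desired_radius_rate",
    "feedback_springs",
    "applied_traction",
]

#: metres/second -> centimetres/hour
M_PER_S_TO_CM_PER_HR = 100.0 * 3600.0


class ControlMode(enum.Enum):
    """Which spring(s) the dilation-rate feedback drives."""

    PIN_ONLY = "pin"
    SLIDING_ONLY = "sliding"
    BOTH = "both"

    @classmethod
    def parse(cls, text: str) -> "ControlMode":
        try:
            return cls(text.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown control mode {text!r}; expected one of {valid}")


@dataclass(frozen=True)
class ControllerConfig:
    """Feedback scenario, gains and setpoint.

    ``desired_diameter_rate`` is stored in SI (m/s); the default is the
    0.692 cm/hr that spreads a 4.5 cm pre-labour dilation over 6.5 steady
    hours.  ``error_unit_scale`` converts the SI rate error into the unit the
    gains act on (default: cm/hr).
    """

    mode: ControlMode = ControlMode.PIN_ONLY
    gain_pin: float = 20.0
    gain_sliding: float = 100000.0
    desired_diameter_rate: float = 0.692 / M_PER_S_TO_CM_PER_HR
    ramp_duration: float = 1800.0
    error_unit_scale: float = M_PER_S_TO_CM_PER_HR
    clamp_nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.gain_pin < 0:
            raise ValueError("gain_pin must be >= 0")
        if self.gain_sliding < 0:
            raise ValueError("gain_sliding must be >= 0")
        if not self.ramp_duration > 0:
            raise ValueError("ramp_duration must be > 0")
        if not self.desired_diameter_rate > 0:
            raise ValueError("desired_diameter_rate must be > 0")
        if not self.error_unit_scale > 0:
            raise ValueError("error_unit_scale must be > 0")


def ramp(t: float, ramp_duration: float) -> float:
    """Cosine smoothstep: 0 at t=0, 1 for t >= ramp_duration, flat ends."""
    if t <= 0.0:
        return 0.0
    if t >= ramp_duration:
        return 1.0
    return 0.5 - 0.5 * math.cos(math.pi * t / ramp_duration)


def desired_radius_rate(t: float, cfg: ControllerConfig) -> float:
    """Setpoint for the radius dilation rate, m/s (half the diameter rate)."""
    return ramp(t, cfg.ramp_duration) * cfg.desired_diameter_rate / 2.0


def feedback_springs(
    measured_radius_rate: float, t: float, cfg: ControllerConfig
) -> tuple[float, float]:
    """Spring constants (K1, K2) from the radius-rate tracking error."""
    error = (
        measured_radius_rate - desired_radius_rate(t, cfg)
    ) * cfg.error_unit_scale
    k1 = cfg.gain_pin * error if cfg.mode is not ControlMode.SLIDING_ONLY else 0.0
    k2 = cfg.gain_sliding * error if cfg.mode is not ControlMode.PIN_ONLY else 0.0
    if cfg.clamp_nonnegative:
        k1 = max(k1, 0.0)
        k2 = max(k2, 0.0)
    return k1, k2


def applied_traction(
    t: float, cfg: ControllerConfig, params: ModelParameters
) -> float:
    """Instantaneous quarter-share traction force, N (ramped)."""
    return ramp(t, cfg.ramp_duration) * traction_force(params)
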