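"""Closed-form reduction of the three constraints to one degree of freedom.

The loop-closure constraints admit the closed-form solution

    thetaR2 = -thetaR1
    sP1     = s_init + l (1 - cos theta)
    sP2     = l sin theta

with theta = thetaR1 in [0, pi/2] as the single reduced coordinate (the
branch containing the closed configuration).  The clinical observables are
the dilation *diameter* 2 sP1 and the effacement sP2; since
sin theta > 1 - cos theta on (0, pi/2), effacement always leads dilation,
as observed clinically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import GeneralizedState, ModelParameters

__all__ = [
    "ReducedState",
    "solve_configuration",
    "configuration_rates",
    "full_state",
    "tangent",
    "dilation_diameter",
    "effacement",
]

_DOMAIN_TOL = 1e-12


@dataclass
class ReducedState:
    """The single reduced coordinate theta (= thetaR1) and its rate."""

    theta: float
    theta_dot: float = 0.0


def _check_domain(theta: float) -> None:
    if not -_DOMAIN_TOL <= theta <= math.pi / 2 + _DOMAIN_TOL:
        raise ValueError(
            f"theta={theta!r} outside the mechanism domain [0, pi/2]"
        )


def solve_configuration(
    theta: float, params: ModelParameters
) -> GeneralizedState:
    """Constraint-consistent positions for a given pin angle theta.

    Raises ``ValueError`` outside [0, pi/2]; the residuals of the returned
    state vanish identically (to round-off).
    """
    _check_domain(theta)
    l = params.wall_thickness_l
    return GeneralizedState(
        sP1=params.s_init + l * (1.0 - math.cos(theta)),
        sP2=l * math.sin(theta),
        thetaR1=theta,
        thetaR2=-theta,
    )


def configuration_rates(
    red: ReducedState, params: ModelParameters
) -> np.ndarray:
    """Rates (sP1_dot, sP2_dot, thetaR1_dot, thetaR2_dot) of the reduction.

    This is the time derivative of :func:`solve_configuration`; the returned
    vector is tangent to the constraint manifold.
    """
    l = params.wall_thickness_l
    th, thd = red.theta, red.theta_dot
    return np.array(
        [l * math.sin(th) * thd, l * math.cos(th) * thd, thd, -thd]
    )


def tangent(theta: float, params: ModelParameters) -> np.ndarray:
    """Admissible-velocity direction J = (l sin, l cos, 1, -1) at theta."""
    l = params.wall_thickness_l
    return np.array([l * math.sin(theta), l * math.cos(theta), 1.0, -1.0])


def full_state(red: ReducedState, params: ModelParameters) -> GeneralizedState:
    """Constraint-consistent positions *and* rates for a reduced state."""
    state = solve_configuration(red.theta, params)
    rates = configuration_rates(red, params)
    state.sP1_dot, state.sP2_dot = rates[0], rates[1]
    state.thetaR1_dot, state.thetaR2_dot = rates[2], rates[3]
    return state


def dilation_diameter(state: GeneralizedState) -> float:
    """Dilation diameter of the canal, m: twice the radial half-opening sP1."""
    return 2.0 * state.sP1


def effacement(state: GeneralizedState) -> float:
    """Effacement (balloon descent / cervical take-up), m: the sP2 coordinate."""
    return state.sP2
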