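"""Core mechanism model of the pregnant cervix quarter-arm.

The cervix is idealised as one of four identical planar arms (a symmetry
quarter), each a rigid link of length ``l`` (the cervical wall thickness)
connected to ground through a pin joint (R1, the anchor to uterus and
endopelvic fascia) and, at its far end, through a second pin joint (R2) to
two orthogonal sliding joints: P1, the radial half-opening of the
endocervical canal, and P2, the vertical descent of the balloon.  Spring-
damper pairs act across R1 (K1, B1) and P1 (K2, B2); a constant share of
the balloon traction force acts along P2.

The configuration is described by four generalized coordinates

    Q = (sP1, sP2, thetaR1, thetaR2)

coupled by three holonomic constraints, leaving a single degree of freedom.
This module assembles the constraint residuals, the (rank-one) mass matrix,
the generalized load vector, the 4x3 constraint-reaction direction matrix
and the analytic constraint Jacobian.  Everything is SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParameters",
    "GeneralizedState",
    "LoadState",
    "ReactionForces",
    "constraint_residuals",
    "constraint_jacobian",
    "constraint_matrix",
    "mass_matrix",
    "load_vector",
    "traction_force",
]


@dataclass(frozen=True)
class ModelParameters:
    """Geometric, inertial, damping and loading constants of the quarter model.

    Parameters
    ----------
    wall_thickness_l:
        Cervical wall thickness = rigid-link length, m.  The at-term wall of a
        4.5 cm wide cervix with a closed canal is 2.25 cm thick, and cervical
        length is taken equal to it.
    s_init:
        Initial radius of the endocervical canal opening, m (0 = closed, no
        funnelling).
    quarter_mass:
        Mass carried by one quarter arm, kg.  One quarter of the 0.027 kg
        at-term cervix estimate, i.e. 0.00675 kg.
    Jzz:
        Rotational inertia of the link about its own centre, kg m^2.  ``None``
        selects the thin-cylinder value (1/12) * quarter_mass * l^2.
    B1, B2:
        Pin-joint damping (N m s / rad) and sliding-joint damping (N s / m).
    g:
        Gravitational acceleration magnitude, m s^-2.
    traction_mass:
        Mass hung from the balloon catheter, kg (clinically ~0.5 kg).
    traction_fraction:
        Share of the traction borne by one quarter arm (0.25).
    gravity_lever_coeff:
        Lever-arm coefficient of the link's weight moment about R1, as a
        fraction of ``l``; 0.5 places the mass at the geometric centre of the
        link.  Exposed for sensitivity analysis.
    """

    wall_thickness_l: float = 0.0225
    s_init: float = 0.0
    quarter_mass: float = 0.00675
    Jzz: float | None = None
    B1: float = 10.0
    B2: float = 10.0
    g: float = 9.81
    traction_mass: float = 0.5
    traction_fraction: float = 0.25
    gravity_lever_coeff: float = 0.5

    def __post_init__(self) -> None:
        if not self.wall_thickness_l > 0:
            raise ValueError("wall_thickness_l must be > 0")
        for name in ("s_init", "quarter_mass", "B1", "B2", "traction_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # Table-style inputs sometimes carry gravity with a sign; only the
        # magnitude enters the equations.
        object.__setattr__(self, "g", abs(float(self.g)))
        if not 0 < self.traction_fraction <= 1:
            raise ValueError("traction_fraction must be in (0, 1]")
        if self.Jzz is None:
            object.__setattr__(self, "Jzz", self.thin_cylinder_Jzz)
        elif self.Jzz < 0:
            raise ValueError("Jzz must be >= 0")

    @property
    def thin_cylinder_Jzz(self) -> float:
        """Thin-cylinder rotational inertia (1/12) m l^2 about the link centre."""
        return self.quarter_mass * self.wall_thickness_l**2 / 12.0

    @property
    def pivot_inertia(self) -> float:
        """Inertia about the R1 pivot: Jzz + m (gravity_lever_coeff*l)^2.

        With the thin-cylinder Jzz and the centred mass this is (1/3) m l^2.
        """
        lever = self.gravity_lever_coeff * self.wall_thickness_l
        return self.Jzz + self.quarter_mass * lever**2


@dataclass
class GeneralizedState:
    """The four generalized coordinates and their rates.

    ``sP1`` is the radial half-opening of the canal (dilation radius), ``sP2``
    the balloon descent (effacement), ``thetaR1``/``thetaR2`` the two pin
    angles.  Arbitrary coordinate values are accepted (root-finding and
    residual evaluation need off-manifold points); constraint consistency is
    a property of states produced by :mod:`cervixsim.kinematics`.
    """

    sP1: float
    sP2: float
    thetaR1: float
    thetaR2: float
    sP1_dot: float = 0.0
    sP2_dot: float = 0.0
    thetaR1_dot: float = 0.0
    thetaR2_dot: float = 0.0

    @property
    def q(self) -> np.ndarray:
        return np.array([self.sP1, self.sP2, self.thetaR1, self.thetaR2])

    @property
    def qdot(self) -> np.ndarray:
        return np.array(
            [self.sP1_dot, self.sP2_dot, self.thetaR1_dot, self.thetaR2_dot]
        )


@dataclass(frozen=True)
class LoadState:
    """Instantaneous spring constants and traction share.

    K1 in N m / rad (pin spring), K2 in N / m (sliding spring), F_traction in
    N (quarter share of the balloon pull).
    """

    K1: float = 0.0
    K2: float = 0.0
    F_traction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "F_traction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ReactionForces:
    """Constraint reactions: forces at pin R2 and moment at slider P1."""

    FxR2: float
    FyR2: float
    MzP1: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.FxR2, self.FyR2, self.MzP1])


def constraint_residuals(
    state: GeneralizedState, params: ModelParameters
) -> np.ndarray:
    """The three holonomic constraint residuals; zero iff consistent.

    The first two close the planar position loop from the R1 anchor through
    the link to the slider pair; the third couples the pin angles
    (it reduces to sin(thetaR1 + thetaR2)).
    """
    l = params.wall_thickness_l
    si = params.s_init
    s1, s2, t1, t2 = state.sP1, state.sP2, state.thetaR1, state.thetaR2
    c1, s1t = math.cos(t1), math.sin(t1)
    return np.array(
        [
            c1 * si + c1 * l - l + s1t * s2 - s1 * math.cos(t2),
            -s1t * si - s1t * l - s1 * math.sin(t2) + c1 * s2,
            math.sin(t1 + t2),
        ]
    )


def constraint_jacobian(
    state: GeneralizedState, params: ModelParameters
) -> np.ndarray:
    """Analytic 3x4 Jacobian of :func:`constraint_residuals` w.r.t. Q."""
    l = params.wall_thickness_l
    si = params.s_init
    s1, s2, t1, t2 = state.sP1, state.sP2, state.thetaR1, state.thetaR2
    c1, sn1 = math.cos(t1), math.sin(t1)
    c2, sn2 = math.cos(t2), math.sin(t2)
    c12 = math.cos(t1 + t2)
    return np.array(
        [
            [-c2, sn1, -sn1 * (si + l) + c1 * s2, s1 * sn2],
            [-sn2, c1, -c1 * (si + l) - sn1 * s2, -s1 * c2],
            [0.0, 0.0, c12, c12],
        ]
    )


def constraint_matrix(
    state: GeneralizedState, params: ModelParameters
) -> np.ndarray:
    """The 4x3 constraint-reaction direction matrix C^T.

    Its columns carry the two R2 reaction-force components and the P1
    reaction moment into the generalized-force space.  On the constraint
    manifold each column equals (up to the reaction sign convention) a row of
    the constraint Jacobian, and every column annihilates the admissible
    velocity tangent, so constraint reactions do no work.
    """
    l = params.wall_thickness_l
    s1, t1, t2 = state.sP1, state.thetaR1, state.thetaR2
    return np.array(
        [
            [math.cos(t2), math.sin(t2), 0.0],
            [-math.sin(t1), -math.cos(t1), 0.0],
            [-s1 * math.sin(t2), l + s1 * math.cos(t2), 1.0],
            [-s1 * math.sin(t2), s1 * math.cos(t2), 1.0],
        ]
    )


def mass_matrix(params: ModelParameters) -> np.ndarray:
    """4x4 generalized mass matrix.

    Only the (thetaR1, thetaR1) entry is non-zero: the link's pivot-axis
    inertia Jzz + m (l/2)^2.  The sliders carry no independent mass, which is
    what makes the unreduced system a genuine DAE (singular mass matrix).
    """
    M = np.zeros((4, 4))
    M[2, 2] = params.pivot_inertia
    return M


def load_vector(
    state: GeneralizedState, loads: LoadState, params: ModelParameters
) -> np.ndarray:
    """Generalized external load vector F.

    Row 1: rectilinear spring-damper force across the canal (K2, B2 on sP1,
    rest length s_init).  Row 2: the traction share, conjugate to the descent
    coordinate.  Row 3: moment about R1 — the link's weight moment plus the
    pin spring-damper (K1, B1).  Row 4: zero (thetaR2 is unloaded).
    """
    p = params
    l = p.wall_thickness_l
    grav_moment = (
        -p.quarter_mass * p.g * p.gravity_lever_coeff * l * math.cos(state.thetaR1)
    )
    return np.array(
        [
            loads.K2 * p.s_init - loads.K2 * state.sP1 - p.B2 * state.sP1_dot,
            loads.F_traction,
            grav_moment - loads.K1 * state.thetaR1 - p.B1 * state.thetaR1_dot,
            0.0,
        ]
    )


def traction_force(params: ModelParameters) -> float:
    """Steady quarter-share traction force: fraction * mass * g (N).

    With the 0.5 kg clinical hanging mass and a quarter share this is
    0.25 * 0.5 * 9.81 = 1.23 N.
    """
    return params.traction_fraction * params.traction_mass * params.g
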