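"""Replicator dynamics of the supervision game.

Each player's strategy frequency grows in proportion to its payoff
advantage over that player's population average::

    dx/dt = x (1 - x) G(y, z)      hospital, compliant operation
    dy/dt = y (1 - y) J(x, z)      third party, true investigation
    dz/dt = z (z - 1) H(x, y)      government, strict supervision

where ``G = E11 - E12``, ``J = E21 - E22`` and ``-H = E31 - E32`` are the
payoff advantages of the first-named strategy.  The factor functions are
exposed separately because the threshold and stability modules reuse
them.

Two dynamics modes are provided.  ``PUBLISHED`` evaluates the closed-form
replicator equations exactly as printed in the study this model
originates from.  ``MATRIX`` derives the factors from the payoff matrix
(:func:`fraudgame.game_model.expected_payoffs`).  The two agree exactly
for the hospital and the government, but the published third-party
factor carries an extra bilinear term ``x*z*(It1 - It2)`` that does not
follow from the payoff matrix; :func:`mode_residual` documents the
difference symbolically.  ``PUBLISHED`` is the default because the
study's stability table and scenario endpoints are only reproduced under
the printed equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .game_model import MixedState, ParameterSet

__all__ = [
    "DynamicsMode",
    "RateVector",
    "G_factor",
    "J_factor",
    "H_factor",
    "vector_field",
    "rates",
    "mode_residual",
]


class DynamicsMode(str, Enum):
    """Which form of the replicator field to evaluate.

    ``PUBLISHED``
        the closed-form equations as printed in the originating study
        (default; reproduces its stability table and scenario endpoints).
    ``MATRIX``
        factors derived from the payoff matrix; differs from
        ``PUBLISHED`` only in the third-party factor, by exactly
        ``x*z*(It1 - It2)``.
    """

    PUBLISHED = "published"
    MATRIX = "matrix"


DEFAULT_MODE = DynamicsMode.PUBLISHED


@dataclass(frozen=True)
class RateVector:
    """Time derivatives (dx/dt, dy/dt, dz/dt) of the mixed state."""

    dx_dt: float
    dy_dt: float
    dz_dt: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx_dt, self.dy_dt, self.dz_dt)


def _check_prob(name: str, value) -> None:
    if np.any(np.asarray(value) < 0) or np.any(np.asarray(value) > 1):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _coerce_mode(mode) -> DynamicsMode:
    return DynamicsMode(mode) if not isinstance(mode, DynamicsMode) else mode


# Internal factor evaluations: no domain checks, accept scalars, numpy
# arrays or sympy expressions alike (the expressions are polynomial).

def _G(p, y, z):
    return (p.Ch2 - p.Ch1 + p.Ih1 - p.Ih2) + z * p.Ah + y * p.Ph + z * p.Ph - y * z * p.Ph


def _J_published(p, x, z):
    return (
        (p.Ct2 - p.Ct1 + p.It1 - p.It2)
        - x * p.It1 + x * p.It2 + z * p.Pt + x * z * p.It1 - x * z * p.It2
    )


def _J_matrix(p, x, z):
    return (p.Ct2 - p.Ct1) + (1 - x) * (p.It1 - p.It2) + z * p.Pt


def _J(p, x, z, mode: DynamicsMode):
    if mode is DynamicsMode.PUBLISHED:
        return _J_published(p, x, z)
    return _J_matrix(p, x, z)


def _H(p, x, y):
    return (
        (p.Cg - p.Ag - p.Pg - p.Ph - p.Pt)
        + x * p.Ah + x * p.Pg + x * p.Ph
        + y * p.Pg + y * p.Ph + y * p.Pt
        - x * y * p.Pg - x * y * p.Ph
    )


def G_factor(params: ParameterSet, y: float, z: float) -> float:
    """Hospital payoff advantage of compliance, ``E11 - E12``.

    Affine-bilinear in (y, z); increasing in both (more scrutiny makes
    compliance relatively more attractive).
    """
    _check_prob("y", y)
    _check_prob("z", z)
    return _G(params, y, z)


def J_factor(params: ParameterSet, x: float, z: float,
             mode: DynamicsMode = DEFAULT_MODE) -> float:
    """Third-party payoff advantage of a true investigation, ``E21 - E22``.

    In ``MATRIX`` mode this is ``Ct2 - Ct1 + (1-x)(It1 - It2) + z*Pt``;
    ``PUBLISHED`` mode adds ``x*z*(It1 - It2)``.
    """
    _check_prob("x", x)
    _check_prob("z", z)
    return _J(params, x, z, _coerce_mode(mode))


def H_factor(params: ParameterSet, x: float, y: float) -> float:
    """Government payoff *disadvantage* of strict supervision, ``E32 - E31``.

    The sign convention follows the replicator equation
    ``dz/dt = z(z-1)H``: strict supervision spreads where ``H < 0``.
    Identical in both dynamics modes.
    """
    _check_prob("x", x)
    _check_prob("y", y)
    return _H(params, x, y)


def vector_field(params: ParameterSet, state: MixedState,
                 mode: DynamicsMode = DEFAULT_MODE) -> RateVector:
    """The replicator rates at ``state``.

    Each component vanishes identically on its own boundary faces, so the
    unit cube is forward-invariant.  Raises :class:`ValueError` outside
    the cube.
    """
    if not isinstance(state, MixedState):
        state = MixedState(*state)
    if not state.in_unit_cube:
        raise ValueError(f"mixed state {state.as_tuple()} outside [0,1]^3")
    mode = _coerce_mode(mode)
    x, y, z = state.as_tuple()
    return RateVector(
        dx_dt=x * (1.0 - x) * _G(params, y, z),
        dy_dt=y * (1.0 - y) * _J(params, x, z, mode),
        dz_dt=z * (z - 1.0) * _H(params, x, y),
    )


def rates(params: ParameterSet, xyz: np.ndarray,
          mode: DynamicsMode = DEFAULT_MODE) -> np.ndarray:
    """Unchecked array form of :func:`vector_field` for ODE integrators.

    ``xyz`` is a length-3 array; values marginally outside [0,1] from
    integrator overshoot are tolerated (the polynomial field extends
    smoothly).
    """
    mode = _coerce_mode(mode)
    x, y, z = xyz
    return np.array([
        x * (1.0 - x) * _G(params, y, z),
        y * (1.0 - y) * _J(params, x, z, mode),
        z * (z - 1.0) * _H(params, x, y),
    ])


@dataclass(frozen=True)
class ModeResidual:
    """Symbolic difference (published minus matrix-derived) per component.

    ``dx`` and ``dz`` are identically zero; ``dy`` equals
    ``y*(1-y)*x*z*(It1 - It2)``.  Attributes are sympy expressions in the
    state symbols x, y, z (numeric parameters substituted in).
    """

    dx: object
    dy: object
    dz: object


def mode_residual(params: ParameterSet | None = None) -> ModeResidual:
    """Symbolically subtract the two dynamics modes, component-wise.

    With ``params`` the sixteen parameter symbols are substituted with
    their numeric values; without, fully symbolic expressions are
    returned.  This is the audit trail for the single point where the
    published closed forms and the payoff-matrix derivation disagree.
    """
    from . import symbolic

    return symbolic.mode_residual(params)
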