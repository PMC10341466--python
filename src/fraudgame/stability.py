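"""Stationary points of the replicator system and their local stability.

The replicator field ``(x(1-x)G, y(1-y)J, z(z-1)H)`` has fifteen
stationary-point candidates: the eight corners of the unit cube, one
candidate per cube face (the two surviving factor equations solved with
the third coordinate fixed at 0 or 1) and one fully interior candidate
(``G = J = H = 0``).  Mixed candidates may fall outside the cube; they
are flagged, not dropped, and — following the scoping of the originating
study — are never classified: an asymptotically stable state of a
multi-population replicator system must be a pure-strategy profile, so
only the corners are run through the first Lyapunov method (sign pattern
of the Jacobian eigenvalues).

At a corner the Jacobian is diagonal, so the eigenvalues are closed-form
affine expressions in the parameters.  ``eigenvalues_at_pure`` returns
them in the row order of the study's stability table (which permutes the
diagonal), so numeric output lines up entry-for-entry with that table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .game_model import MixedState, ParameterSet, validate_parameters
from .replicator import DEFAULT_MODE, DynamicsMode, _G, _H, _J, _coerce_mode

__all__ = [
    "EquilibriumPoint",
    "EigenTriple",
    "StabilityClass",
    "ConditionFlags",
    "StabilityReport",
    "CORNER_COORDS",
    "pure_equilibria",
    "candidate_equilibria",
    "jacobian_at",
    "eigenvalues_at_pure",
    "classify",
    "condition_flags",
    "ess_set",
    "stability_report",
]

#: Corner labels and coordinates, in stability-table order.
CORNER_COORDS: dict[str, tuple[float, float, float]] = {
    "E1": (0.0, 0.0, 0.0),
    "E2": (1.0, 0.0, 0.0),
    "E3": (0.0, 1.0, 0.0),
    "E4": (0.0, 0.0, 1.0),
    "E5": (1.0, 1.0, 0.0),
    "E6": (1.0, 0.0, 1.0),
    "E7": (0.0, 1.0, 1.0),
    "E8": (1.0, 1.0, 1.0),
}

# The stability table lists each corner's eigenvalues in its own order,
# a permutation of the Jacobian diagonal (d/dx, d/dy, d/dz) entries.
_ROW_ORDER: dict[str, tuple[int, int, int]] = {
    "E1": (0, 1, 2),
    "E2": (1, 2, 0),
    "E3": (2, 1, 0),
    "E4": (2, 1, 0),
    "E5": (1, 2, 0),
    "E6": (2, 1, 0),
    "E7": (2, 1, 0),
    "E8": (2, 1, 0),
}


@dataclass(frozen=True)
class EquilibriumPoint:
    """A stationary-point candidate.

    Corners carry labels E1..E8; the six face candidates A9..A14 and the
    interior candidate A15.  ``state`` may lie outside the unit cube
    (``in_domain`` is then False) or be undefined when the factor
    equations degenerate (``defined`` False, with a ``reason``).
    """

    label: str
    state: MixedState | None
    in_domain: bool
    defined: bool = True
    reason: str | None = None

    @property
    def is_corner(self) -> bool:
        return self.label in CORNER_COORDS


class StabilityClass(str, Enum):
    ESS = "ESS"
    UNSTABLE = "unstable"
    SADDLE = "saddle"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class EigenTriple:
    """Jacobian eigenvalues (real, the corner Jacobian is diagonal)."""

    lam1: float
    lam2: float
    lam3: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lam1, self.lam2, self.lam3)


@dataclass(frozen=True)
class ConditionFlags:
    """The three parameter conditions under which a corner can be ESS.

    A: ``Cg > Ag + Pg + Ph + Pt`` — supervision too costly, (0,0,0) stable.
    B: ``Pt < Ct1 - Ct2 + It2 - It1`` and ``Ah + Ph < Ch1 - Ch2 + Ih2 - Ih1``
       — instruments too weak to deter anyone, (0,0,1) stable.
    C: ``Ah + Cg < Ag + Pt`` — supervision pays for itself, (1,0,1) stable.
    """

    A: bool
    B: bool
    C: bool


def pure_equilibria() -> list[EquilibriumPoint]:
    """The eight pure-strategy corners, in table order."""
    return [
        EquilibriumPoint(label, MixedState(*coords), in_domain=True)
        for label, coords in CORNER_COORDS.items()
    ]


def _solve_linear(f: Callable[[float], float]) -> tuple[float | None, str | None]:
    """Root of the affine map v -> f(v) probed at v=0 and v=1."""
    f0, f1 = f(0.0), f(1.0)
    slope = f1 - f0
    if abs(slope) < 1e-12:
        if abs(f0) < 1e-12:
            return None, "factor vanishes identically (continuum of stationary points)"
        return None, "factor does not depend on the free coordinate"
    return -f0 / slope, None


def _bilinear_coeffs(f: Callable[[float, float], float]) -> tuple[float, float, float, float]:
    """(c00, cu, cv, cuv) of a bilinear f(u,v) probed at the corners."""
    f00, f10, f01, f11 = f(0.0, 0.0), f(1.0, 0.0), f(0.0, 1.0), f(1.0, 1.0)
    return f00, f10 - f00, f01 - f00, f11 - f10 - f01 + f00


def _interior_candidate(params: ParameterSet, mode: DynamicsMode) -> EquilibriumPoint:
    """Solve G = J = H = 0 by elimination.

    G(y,z)=0 and J(x,z)=0 are affine in y and x respectively, giving
    rational y(z), x(z); substituting into the bilinear H and clearing
    denominators leaves a quadratic in z, solved exactly.  Among the real
    roots, an in-cube solution is preferred; ties break on the smallest z
    (then y, then x) so the choice is deterministic.
    """
    g00, gy, gz, gyz = _bilinear_coeffs(lambda y, z: _G(params, y, z))
    j00, jx, jz, jxz = _bilinear_coeffs(lambda x, z: _J(params, x, z, mode))
    h00, hx, hy, hxy = _bilinear_coeffs(lambda x, y: _H(params, x, y))

    # y(z) = C(z)/D(z), x(z) = A(z)/B(z); coeff arrays are [slope, const]
    C = np.array([-gz, -g00])
    D = np.array([gyz, gy])
    A = np.array([-jz, -j00])
    B = np.array([jxz, jx])

    poly = (
        h00 * np.convolve(B, D)
        + hx * np.convolve(A, D)
        + hy * np.convolve(C, B)
        + hxy * np.convolve(A, C)
    )
    scale = np.max(np.abs(poly))
    if scale < 1e-12:
        return EquilibriumPoint("A15", None, in_domain=False, defined=False,
                                reason="degenerate system: continuum of interior candidates")
    coeffs = np.trim_zeros(np.where(np.abs(poly / scale) < 1e-14, 0.0, poly), "f")
    if coeffs.size <= 1:
        return EquilibriumPoint("A15", None, in_domain=False, defined=False,
                                reason="no interior solution: eliminant has no root")
    roots = np.roots(coeffs)
    solutions: list[tuple[float, float, float]] = []
    for r in roots:
        if abs(r.imag) > 1e-9 * (1.0 + abs(r)):
            continue
        z = float(r.real)
        bden, dden = np.polyval(B, z), np.polyval(D, z)
        if abs(bden) < 1e-12 or abs(dden) < 1e-12:
            continue
        x = float(np.polyval(A, z) / bden)
        y = float(np.polyval(C, z) / dden)
        solutions.append((x, y, z))
    if not solutions:
        return EquilibriumPoint("A15", None, in_domain=False, defined=False,
                                reason="no real interior solution")

    def in_cube(s: tuple[float, float, float]) -> bool:
        return all(0.0 <= v <= 1.0 for v in s)

    solutions.sort(key=lambda s: (not in_cube(s), s[2], s[1], s[0]))
    x, y, z = solutions[0]
    return EquilibriumPoint("A15", MixedState(x, y, z), in_domain=in_cube((x, y, z)))


# Per cube face: (label, fixed axis, fixed value). The two free
# coordinates solve the factor equations that do not vanish on the face.
_FACES = (
    ("A9", "x", 0.0), ("A10", "x", 1.0),
    ("A11", "y", 0.0), ("A12", "y", 1.0),
    ("A13", "z", 0.0), ("A14", "z", 1.0),
)


def candidate_equilibria(params: ParameterSet,
                         mode: DynamicsMode = DEFAULT_MODE) -> list[EquilibriumPoint]:
    """All fifteen stationary-point candidates.

    Eight corners (always in-domain), six face candidates and one
    interior candidate.  Out-of-cube coordinates are flagged via
    ``in_domain``; degenerate solves yield ``defined=False`` with a
    reason instead of being silently dropped, so the census always has
    fifteen entries.
    """
    mode = _coerce_mode(mode)
    points = pure_equilibria()
    for label, axis, value in _FACES:
        if axis == "x":
            y, reason_y = _solve_linear(lambda v: _H(params, value, v))
            z, reason_z = _solve_linear(lambda v: _J(params, value, v, mode))
            coords, reason = (value, y, z), reason_y or reason_z
        elif axis == "y":
            z, reason_z = _solve_linear(lambda v: _G(params, value, v))
            x, reason_x = _solve_linear(lambda v: _H(params, v, value))
            coords, reason = (x, value, z), reason_z or reason_x
        else:
            y, reason_y = _solve_linear(lambda v: _G(params, v, value))
            x, reason_x = _solve_linear(lambda v: _J(params, v, value, mode))
            coords, reason = (x, y, value), reason_y or reason_x
        if reason is not None or any(c is None for c in coords):
            points.append(EquilibriumPoint(label, None, in_domain=False,
                                           defined=False, reason=reason))
        else:
            state = MixedState(*coords)
            points.append(EquilibriumPoint(label, state, in_domain=state.in_unit_cube))
    points.append(_interior_candidate(params, mode))
    return points


def jacobian_at(params: ParameterSet, state: MixedState,
                mode: DynamicsMode = DEFAULT_MODE) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator field at ``state``."""
    if not isinstance(state, MixedState):
        state = MixedState(*state)
    if not state.in_unit_cube:
        raise ValueError(f"mixed state {state.as_tuple()} outside [0,1]^3")
    mode = _coerce_mode(mode)
    p = params
    x, y, z = state.as_tuple()

    G = _G(p, y, z)
    J = _J(p, x, z, mode)
    H = _H(p, x, y)
    dG_dy = p.Ph * (1.0 - z)
    dG_dz = p.Ah + p.Ph * (1.0 - y)
    if mode is DynamicsMode.PUBLISHED:
        dJ_dx = (p.It2 - p.It1) * (1.0 - z)
        dJ_dz = p.Pt + x * (p.It1 - p.It2)
    else:
        dJ_dx = p.It2 - p.It1
        dJ_dz = p.Pt
    dH_dx = p.Ah + p.Pg + p.Ph - y * (p.Pg + p.Ph)
    dH_dy = (p.Pg + p.Ph) * (1.0 - x) + p.Pt

    return np.array([
        [(1.0 - 2.0 * x) * G, x * (1.0 - x) * dG_dy, x * (1.0 - x) * dG_dz],
        [y * (1.0 - y) * dJ_dx, (1.0 - 2.0 * y) * J, y * (1.0 - y) * dJ_dz],
        [z * (z - 1.0) * dH_dx, z * (z - 1.0) * dH_dy, (2.0 * z - 1.0) * H],
    ])


def _resolve_corner(point: EquilibriumPoint | str) -> tuple[str, tuple[float, float, float]]:
    label = point.label if isinstance(point, EquilibriumPoint) else str(point)
    if label not in CORNER_COORDS:
        raise ValueError(
            f"{label!r} is not a pure-strategy corner; mixed candidates are not classified"
        )
    return label, CORNER_COORDS[label]


def eigenvalues_at_pure(params: ParameterSet, point: EquilibriumPoint | str,
                        mode: DynamicsMode = DEFAULT_MODE) -> EigenTriple:
    """Eigenvalues at a corner, in stability-table row order.

    The corner Jacobian is diagonal, so these are exact; the per-corner
    permutation makes the output comparable entry-for-entry with the
    table's closed forms.
    """
    label, coords = _resolve_corner(point)
    diag = np.diag(jacobian_at(params, MixedState(*coords), mode))
    order = _ROW_ORDER[label]
    return EigenTriple(*(float(diag[i]) for i in order))


def classify(params: ParameterSet, point: EquilibriumPoint | str,
             mode: DynamicsMode = DEFAULT_MODE, tol: float = 1e-9) -> StabilityClass:
    """First-Lyapunov classification of a corner.

    All eigenvalues below ``-tol``: ESS (asymptotically stable); all
    above ``+tol``: unstable; strict mixed signs: saddle.  Any eigenvalue
    within ``±tol`` of zero: indeterminate — the linearization is
    inconclusive there and no class is guessed.
    """
    lams = eigenvalues_at_pure(params, point, mode).as_tuple()
    if any(abs(l) <= tol for l in lams):
        return StabilityClass.INDETERMINATE
    if all(l < 0 for l in lams):
        return StabilityClass.ESS
    if all(l > 0 for l in lams):
        return StabilityClass.UNSTABLE
    return StabilityClass.SADDLE


def condition_flags(params: ParameterSet) -> ConditionFlags:
    """Evaluate the ESS conditions A, B, C at ``params``."""
    p = params
    return ConditionFlags(
        A=p.Cg > p.Ag + p.Pg + p.Ph + p.Pt,
        B=(p.Pt < p.Ct1 - p.Ct2 + p.It2 - p.It1)
          and (p.Ah + p.Ph < p.Ch1 - p.Ch2 + p.Ih2 - p.Ih1),
        C=p.Ah + p.Cg < p.Ag + p.Pt,
    )


def ess_set(params: ParameterSet, mode: DynamicsMode = DEFAULT_MODE,
            tol: float = 1e-9) -> list[EquilibriumPoint]:
    """Corners classified ESS (a subset of {E1, E4, E6} for valid strict
    parameters under the published dynamics)."""
    return [
        point for point in pure_equilibria()
        if classify(params, point, mode, tol) is StabilityClass.ESS
    ]


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues and classification of every corner, plus the flags."""

    labels: Sequence[str]
    eigenvalues: Sequence[EigenTriple]
    classes: Sequence[StabilityClass]
    flags: ConditionFlags
    mode: DynamicsMode = DEFAULT_MODE

    def to_dataframe(self) -> pd.DataFrame:
        flags = self.flags
        return pd.DataFrame({
            "point": list(self.labels),
            "lambda1": [e.lam1 for e in self.eigenvalues],
            "lambda2": [e.lam2 for e in self.eigenvalues],
            "lambda3": [e.lam3 for e in self.eigenvalues],
            "class": [c.value for c in self.classes],
            "condA": flags.A,
            "condB": flags.B,
            "condC": flags.C,
        })


def stability_report(params: ParameterSet, mode: DynamicsMode = DEFAULT_MODE,
                     tol: float = 1e-9) -> StabilityReport:
    """Classify all eight corners and evaluate the condition flags."""
    violations = validate_parameters(params)
    if violations:
        raise ValueError(f"invalid parameters: {', '.join(violations)}")
    mode = _coerce_mode(mode)
    labels = list(CORNER_COORDS)
    eigs = [eigenvalues_at_pure(params, label, mode) for label in labels]
    classes = [classify(params, label, mode, tol) for label in labels]
    return StabilityReport(labels, eigs, classes, condition_flags(params), mode)
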