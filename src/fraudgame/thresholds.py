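"""Indifference surfaces, their intercept geometry and sensitivity signs.

Each player is indifferent where its factor function vanishes:

* ``y*(z)`` — the true-investigation probability at which the hospital is
  indifferent (``G = 0``);
* ``x*(z)`` — the compliance probability at which the third party is
  indifferent (``J = 0``);
* ``y**(x)`` — the true-investigation probability at which the
  government is indifferent (``H = 0``).

On the relevant unit square, each curve splits the opponent-strategy
space into a basin where the player's strategy probability evolves to 0
and one where it evolves to 1.  The study approximates each basin by the
triangle cut off by the curve's axis intercepts; because the curves are
hyperbolic and the intercepts can exceed 1, the package reports both
that triangle approximation (clipped to [0, 1] and flagged when
clipping occurred) and a numerical-quadrature reference measure of the
exact sub-level region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import sympy as sp

from .game_model import ParameterSet, PARAMETER_NAMES, validate_parameters
from .replicator import DEFAULT_MODE, DynamicsMode, _coerce_mode, _G, _H, _J

__all__ = [
    "ThresholdGeometry",
    "SensitivitySignTable",
    "y_star",
    "x_star",
    "y_double_star",
    "threshold_geometry",
    "sensitivity_signs",
]

#: midpoint-rule resolution per axis for the integral method; the
#: resulting area error is far below the 1e-3 tolerance used in tests
QUADRATURE_GRID = 512


def _require_strict(params: ParameterSet) -> None:
    violations = validate_parameters(params, strict=True)
    if violations:
        raise ValueError(f"strict parameter validation failed: {', '.join(violations)}")


def y_star(params: ParameterSet, z: float) -> float:
    """Hospital indifference threshold on the (z, y) face.

    The root in y of ``G(y, z) = 0``; below it compliance dies out
    (x -> 0), above it compliance takes over (x -> 1).  Undefined at
    z = 1, where G no longer depends on y.
    """
    _require_strict(params)
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"z must lie in [0, 1], got {z!r}")
    p = params
    denom = p.Ph * (z - 1.0)
    if denom == 0.0:
        raise ZeroDivisionError("y* is undefined at z = 1 (G does not depend on y there)")
    return (p.Ch2 - p.Ch1 + p.Ih1 - p.Ih2 + z * p.Ah + z * p.Ph) / denom


def x_star(params: ParameterSet, z: float,
           mode: DynamicsMode = DEFAULT_MODE) -> float:
    """Third-party indifference threshold on the (z, x) face.

    The root in x of ``J(x, z) = 0``.  In the published mode the
    denominator ``(It1 - It2)(1 - z)`` vanishes at z = 1; in the matrix
    mode it is the constant ``It1 - It2``.
    """
    _require_strict(params)
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"z must lie in [0, 1], got {z!r}")
    mode = _coerce_mode(mode)
    p = params
    numer = p.Ct2 - p.Ct1 + p.It1 - p.It2 + z * p.Pt
    if mode is DynamicsMode.PUBLISHED:
        denom = (p.It1 - p.It2) * (1.0 - z)
        if denom == 0.0:
            raise ZeroDivisionError("x* is undefined at z = 1 in the published dynamics")
    else:
        denom = p.It1 - p.It2
    return numer / denom


def y_double_star(params: ParameterSet, x: float) -> float:
    """Government indifference threshold on the (x, y) face.

    The root in y of ``H(x, y) = 0``; below it strict supervision is
    worthwhile (z -> 1), above it the government disengages (z -> 0).
    The denominator ``(Pg + Ph)(1 - x) + Pt`` is positive for strict
    parameters, so the threshold is always defined (though it may fall
    outside [0, 1]).
    """
    _require_strict(params)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x!r}")
    p = params
    numer = p.Ag - p.Cg + p.Pg + p.Ph + p.Pt - x * p.Ah - x * p.Pg - x * p.Ph
    denom = p.Pg + p.Ph + p.Pt - x * (p.Pg + p.Ph)
    return numer / denom


@dataclass(frozen=True)
class ThresholdGeometry:
    """Axis intercepts, segment lengths and basin measures.

    Intercepts store the nonzero coordinate of each labelled point (B1,
    C1 for ``y*``; B2, C2 for ``x*``; B3, C3 for ``y**``) and may exceed
    1.  ``Vh2`` measures the hospital's illegal-operation basin on the
    (y, z) square, ``Vt2`` the false-investigation basin on (x, z), and
    ``Vg1`` the strict-supervision basin on (x, y); each complement sums
    to 1.  ``clipped`` flags measures whose triangle approximation had
    to be clipped into [0, 1].
    """

    B1: float
    C1: float
    B2: float
    C2: float
    B3: float
    C3: float
    A1B1: float
    A1C1: float
    A2B2: float
    A2C2: float
    A3B3: float
    A3C3: float
    Vh1: float
    Vh2: float
    Vt1: float
    Vt2: float
    Vg1: float
    Vg2: float
    method: Literal["triangle", "integral"]
    clipped: tuple[str, ...] = ()


def _segments(params: ParameterSet) -> dict[str, float]:
    """Closed-form intercepts and segment lengths (unclipped)."""
    p = params
    n1 = p.Ch1 - p.Ch2 - p.Ih1 + p.Ih2
    n2 = p.Ct1 - p.Ct2 - p.It1 + p.It2
    n3 = p.Ag - p.Cg + p.Pg + p.Ph + p.Pt
    return {
        "B1": n1 / p.Ph, "C1": n1 / (p.Ah + p.Ph),
        "B2": n2 / p.Pt, "C2": n2 / (p.It2 - p.It1),
        "B3": n3 / (p.Ah + p.Pg + p.Ph), "C3": n3 / (p.Pg + p.Ph + p.Pt),
        "A1B1": n1 / (p.Ah + p.Ph), "A1C1": n1 / p.Ph,
        "A2B2": n2 / p.Pt, "A2C2": n2 / (p.It2 - p.It1),
        "A3B3": n3 / (p.Ah + p.Pg + p.Ph), "A3C3": n3 / (p.Pg + p.Ph + p.Pt),
    }


def _triangle_measures(seg: Mapping[str, float]) -> tuple[dict[str, float], list[str]]:
    clipped: list[str] = []

    def area(l1: float, l2: float, name: str) -> float:
        # both intercepts share the sign of the numerator; a non-positive
        # numerator means the curve misses the positive quadrant and the
        # sub-level region is empty
        if l1 <= 0.0 or l2 <= 0.0:
            if l1 < 0.0 or l2 < 0.0:
                clipped.append(name)
            return 0.0
        s = 0.5 * l1 * l2
        if s >= 1.0:
            clipped.append(name)
            return 1.0
        return s

    vh2 = area(seg["A1B1"], seg["A1C1"], "Vh2")
    vt2 = area(seg["A2B2"], seg["A2C2"], "Vt2")
    vg1 = area(seg["A3B3"], seg["A3C3"], "Vg1")
    return {"Vh2": vh2, "Vt2": vt2, "Vg1": vg1}, clipped


def _integral_measures(params: ParameterSet, mode: DynamicsMode) -> dict[str, float]:
    n = QUADRATURE_GRID
    mid = (np.arange(n) + 0.5) / n
    u, v = np.meshgrid(mid, mid, indexing="ij")
    vh2 = float(np.mean(_G(params, u, v) < 0.0))          # (y, z) square
    vt2 = float(np.mean(_J(params, u, v, mode) < 0.0))    # (x, z) square
    vg1 = float(np.mean(_H(params, u, v) < 0.0))          # (x, y) square
    return {"Vh2": vh2, "Vt2": vt2, "Vg1": vg1}


def threshold_geometry(params: ParameterSet,
                       method: Literal["triangle", "integral"] = "triangle",
                       mode: DynamicsMode = DEFAULT_MODE) -> ThresholdGeometry:
    """Intercepts, segment lengths and basin measures for ``params``.

    ``method='triangle'`` uses the closed-form intercept triangles
    (clipped into [0, 1]); ``method='integral'`` measures the exact
    factor sub-level regions by midpoint quadrature on a
    ``QUADRATURE_GRID``-squared grid.  Requires strictly valid
    parameters (the formulas divide by the fines and the bribe margin).
    """
    _require_strict(params)
    if method not in ("triangle", "integral"):
        raise ValueError(f"unknown method {method!r}")
    seg = _segments(params)
    if method == "triangle":
        measures, clipped = _triangle_measures(seg)
    else:
        measures, clipped = _integral_measures(params, _coerce_mode(mode)), []
    return ThresholdGeometry(
        **{k: seg[k] for k in ("B1", "C1", "B2", "C2", "B3", "C3",
                               "A1B1", "A1C1", "A2B2", "A2C2", "A3B3", "A3C3")},
        Vh2=measures["Vh2"], Vh1=1.0 - measures["Vh2"],
        Vt2=measures["Vt2"], Vt1=1.0 - measures["Vt2"],
        Vg1=measures["Vg1"], Vg2=1.0 - measures["Vg1"],
        method=method, clipped=tuple(clipped),
    )


@dataclass(frozen=True)
class SensitivitySignTable:
    """Signs (and values) of the partial derivatives of the geometry.

    ``signs[(quantity, parameter)]`` is "+", "-" or "0"; ``derivatives``
    holds the underlying numeric partials.  Quantities cover the six
    segment lengths and the six region measures (triangle form).
    """

    signs: Mapping[tuple[str, str], str]
    derivatives: Mapping[tuple[str, str], float]


_SYMS = dict(zip(PARAMETER_NAMES, sp.symbols(" ".join(PARAMETER_NAMES), positive=True)))


def _symbolic_geometry() -> dict[str, sp.Expr]:
    s = sp.Symbol
    p = type("P", (), {name: sym for name, sym in _SYMS.items()})
    n1 = p.Ch1 - p.Ch2 - p.Ih1 + p.Ih2
    n2 = p.Ct1 - p.Ct2 - p.It1 + p.It2
    n3 = p.Ag - p.Cg + p.Pg + p.Ph + p.Pt
    seg = {
        "A1B1": n1 / (p.Ah + p.Ph), "A1C1": n1 / p.Ph,
        "A2B2": n2 / p.Pt, "A2C2": n2 / (p.It2 - p.It1),
        "A3B3": n3 / (p.Ah + p.Pg + p.Ph), "A3C3": n3 / (p.Pg + p.Ph + p.Pt),
    }
    seg["Vh2"] = seg["A1B1"] * seg["A1C1"] / 2
    seg["Vh1"] = 1 - seg["Vh2"]
    seg["Vt2"] = seg["A2B2"] * seg["A2C2"] / 2
    seg["Vt1"] = 1 - seg["Vt2"]
    seg["Vg1"] = seg["A3B3"] * seg["A3C3"] / 2
    seg["Vg2"] = 1 - seg["Vg1"]
    return seg


_GEOMETRY_EXPRS = _symbolic_geometry()


def sensitivity_signs(params: ParameterSet, tol: float = 1e-12,
                      fd_step: float = 1e-6) -> SensitivitySignTable:
    """Partial-derivative signs of the threshold geometry at ``params``.

    Differentiates the closed-form segment lengths and unclipped triangle
    measures symbolically, evaluates at ``params`` and cross-checks each
    value with a central finite difference; a disagreement in sign raises
    (it would indicate an algebra error, not a data problem).  For a
    region whose triangle is empty at ``params`` (negative intercepts)
    the true local sensitivity is zero and is reported as "0".
    """
    _require_strict(params)
    subs = {sym: getattr(params, name) for name, sym in _SYMS.items()}
    n3 = params.Ag - params.Cg + params.Pg + params.Ph + params.Pt
    empty_regions = {"Vg1", "Vg2"} if n3 <= 0 else set()

    signs: dict[tuple[str, str], str] = {}
    derivs: dict[tuple[str, str], float] = {}
    for qname, expr in _GEOMETRY_EXPRS.items():
        for pname, sym in _SYMS.items():
            if sym not in expr.free_symbols:
                continue
            key = (qname, pname)
            if qname in empty_regions:
                signs[key] = "0"
                derivs[key] = 0.0
                continue
            value = float(sp.diff(expr, sym).subs(subs))
            fd = _finite_difference(expr, sym, subs, fd_step)
            if value * fd < 0 and max(abs(value), abs(fd)) > 1e-6:
                raise AssertionError(
                    f"finite-difference check failed for d{qname}/d{pname}: "
                    f"closed form {value:g}, finite difference {fd:g}"
                )
            derivs[key] = value
            signs[key] = "0" if abs(value) <= tol else ("+" if value > 0 else "-")
    return SensitivitySignTable(signs=signs, derivatives=derivs)


def _finite_difference(expr: sp.Expr, sym: sp.Symbol, subs: dict, h: float) -> float:
    base = float(subs[sym])
    step = h * max(1.0, abs(base))
    hi = dict(subs)
    hi[sym] = base + step
    lo = dict(subs)
    lo[sym] = base - step
    return (float(expr.subs(hi)) - float(expr.subs(lo))) / (2.0 * step)
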